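"""Analysis configuration.

One flat record of every tunable the pipeline uses, serialized alongside
results for reproducibility.  Defaults follow the standard voxelwise
max-statistic permutation setup (alpha 0.05, 1000 permutations) and the
90th-percentile hub rule.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    #: seed sphere radius around each stimulation point, mm
    seed_radius_mm: float = 3.0
    #: familywise significance level for the permutation test
    alpha: float = 0.05
    #: sign-flip permutations (exhaustive enumeration used when 2^n <= n_perm)
    n_perm: int = 1000
    #: percentile of positive in-grey-matter frequencies defining hub territory
    hub_percentile: float = 90.0
    #: kernel radius of the points-only probabilistic atlas, mm
    atlas_radius_mm: float = 5.0
    #: frequency threshold (percent of seeds) for binarizing networks
    network_threshold: float = 50.0
    #: surrogates for spatial-autocorrelation-corrected map similarity
    n_surrogates: int = 1000
    #: bootstrap iterations for the clinical-vs-reference effect-size test
    n_boot: int = 100_000
    #: subjects drawn per bootstrap iteration
    boot_sample_size: int = 66
    #: master random seed
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_radius_mm < 0:
            raise ValueError("seed_radius_mm must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_perm", "n_surrogates", "n_boot", "boot_sample_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.hub_percentile <= 100:
            raise ValueError("hub_percentile must be in (0, 100]")
        if self.atlas_radius_mm <= 0:
            raise ValueError("atlas_radius_mm must be > 0")
        if not 0 <= self.network_threshold <= 100:
            raise ValueError("network_threshold must be in [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "AnalysisConfig":
        d = self.to_dict()
        d.update(kw)
        return AnalysisConfig(**d)


def load_config(path) -> AnalysisConfig:
    """Load a flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
    return AnalysisConfig(**raw)


def save_config(path, config: AnalysisConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
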