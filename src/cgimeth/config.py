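"""Configuration objects for the synthetic cohort and the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

REGIONS = ("N_shelf", "N_shore", "island", "S_shore", "S_shelf")
ARCHETYPES = ("cluster1", "cluster2", "cluster3up", "cluster3down")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults define the study conditions used throughout the test suite: a
    cohort of 100 CGI+SS loci with matched normal/cancer samples, beta-value
    noise of array-like precision, a CIMP subgroup covering half of the
    cancer samples, and survival hazards matching the breast-cancer Cox fit
    (intermediate-methylation group at highest risk).
    """

    n_samples_normal: int = 100
    n_samples_cancer: int = 100
    n_cgi: int = 100
    probes_per_cgi_range: tuple[int, int] = (10, 40)
    # fractions over (cluster1, cluster2, cluster3up, cluster3down)
    archetype_fractions: tuple[float, float, float, float] = (0.60, 0.15, 0.15, 0.10)
    cimp_fraction: float = 0.3
    cimp_drift_sd: float = 0.03
    beta_noise_concentration: float = 50.0
    n_regulated_genes: int = 20
    effect_region: str = "S_shore"
    effect_probes_per_gene: int = 3
    effect_size: float = 3.0
    expression_noise_sd: float = 0.3
    cnv_effect_size: float = 1.0
    cnv_sensitive_fraction: float = 0.5
    hazard_ratio_intermediate: float = 3.44
    hazard_ratio_high: float = 1.92
    baseline_hazard_per_year: float = 0.18
    censor_years: float = 5.0
    multi_cgi_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.probes_per_cgi_range = tuple(self.probes_per_cgi_range)  # type: ignore[assignment]
        self.archetype_fractions = tuple(self.archetype_fractions)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.archetype_fractions) - 1.0) > 1e-9:
            raise ValueError("archetype_fractions must sum to 1")
        if len(self.archetype_fractions) != 4:
            raise ValueError("archetype_fractions needs 4 entries "
                             "(cluster1, cluster2, cluster3up, cluster3down)")
        for name in ("n_samples_normal", "n_samples_cancer", "n_cgi",
                     "n_regulated_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.probes_per_cgi_range
        if not (1 <= lo <= hi):
            raise ValueError("probes_per_cgi_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.cimp_fraction <= 1.0:
            raise ValueError("cimp_fraction must be in [0, 1]")
        if self.beta_noise_concentration <= 0:
            raise ValueError("beta_noise_concentration must be positive")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be >= 0")
        if self.effect_region not in REGIONS:
            raise ValueError(f"effect_region must be one of {REGIONS}")
        if self.hazard_ratio_intermediate <= 0 or self.hazard_ratio_high <= 0:
            raise ValueError("hazard ratios must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["probes_per_cgi_range"] = list(self.probes_per_cgi_range)
        d["archetype_fractions"] = list(self.archetype_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one structured file, one master seed)."""

    out_dir: str = "cgimeth_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # stage toggles
    run_profiles: bool = True
    run_cluster: bool = True
    run_associate: bool = True
    run_cnv: bool = True
    run_survival: bool = True
    # stage parameters
    min_probes: int = 20
    k_normal: int | str = 2
    k_cancer: int | str = 3
    bootstrap_repeats: int = 100
    bootstrap_subsample: float = 0.8
    cv_folds: int = 3
    cv_repeats: int = 10
    top_n: int = 20
    window_years: float = 5.0
    models: tuple[str, ...] = ("ols_mean", "lasso_full")

    def __post_init__(self) -> None:
        if isinstance(self.sim, Mapping):
            self.sim = SimConfig.from_dict(self.sim)
        self.models = tuple(self.models)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
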