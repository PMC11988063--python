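"""Configuration objects for simulation, MCMC and the end-to-end pipeline.

Defaults reproduce the study conditions of the smallholder crossbred
test-day analysis this package implements: herd sizes overwhelmingly of one
or two cows, monthly fat% records within days 8-340 of lactation, additive
genetic variance 0.012 and residual variance 0.106 (fat%^2), 50K-style
biallelic genotypes, and a four-component BayesR mixture of SNP effects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

__all__ = [
    "SMALLHOLDER_HERD_SIZE_COUNTS",
    "SimConfig",
    "DefectSpec",
    "MCMCConfig",
    "PhenoQCConfig",
    "GenoQCConfig",
    "PipelineConfig",
]

#: Published herd-size composition (herd size 1..6 and "7 and above"):
#: number of herds per size class in the smallholder study population.
SMALLHOLDER_HERD_SIZE_COUNTS: tuple[int, ...] = (839, 297, 79, 21, 15, 5, 4)

_TOTAL_HERDS = sum(SMALLHOLDER_HERD_SIZE_COUNTS)  # 1260
#: The same composition as a probability vector over sizes 1..7.
SMALLHOLDER_HERD_SIZE_PROBS: tuple[float, ...] = tuple(
    c / _TOTAL_HERDS for c in SMALLHOLDER_HERD_SIZE_COUNTS
)

# Study-scale ratio of farms to community development centres (1659/75).
_HERDS_PER_CDC = 22


@dataclass
class SimConfig:
    """Ground-truth simulation settings for a smallholder population.

    Variance components are in fat%^2; ``herd_size_distribution[k]`` is the
    probability that a herd holds ``k+1`` cows; ``mixture_variance_scales``
    are fractions of the total genic variance assigned to each BayesR
    mixture class (class 1 is the exact-zero class).
    """

    n_herds: int = 330
    herd_size_distribution: tuple[float, ...] = SMALLHOLDER_HERD_SIZE_PROBS
    n_cdcs: int | None = None          # default: ~1 CDC per 22 herds
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    legendre_order: int = 0
    variance_components: dict = field(
        default_factory=lambda: {"Va": 0.012, "Vpe": 0.0, "Vherd": 0.0, "Ve": 0.106}
    )
    mixture_proportions: tuple[float, ...] = (0.95, 0.03, 0.015, 0.005)
    mixture_variance_scales: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    standardize_genic_variance: bool = True
    records_per_lactation: int = 8
    dim_window: tuple[int, int] = (8, 340)
    base_fat_pct: float = 4.5
    n_lactations: int = 1
    jitter_test_days: bool = False
    fixed_effect_sd: dict = field(
        default_factory=lambda: {"lactation": 0.05, "cdc": 0.05, "year_month": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_herds < 1:
            raise ValueError("n_herds must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        dist = np.asarray(self.herd_size_distribution, dtype=float)
        if dist.size == 0:
            raise ValueError("herd_size_distribution is empty")
        if (dist < 0).any() or abs(dist.sum() - 1.0) > 1e-12:
            raise ValueError("herd_size_distribution must be non-negative and sum to 1")
        mix = np.asarray(self.mixture_proportions, dtype=float)
        if abs(mix.sum() - 1.0) > 1e-12 or (mix < 0).any():
            raise ValueError("mixture_proportions must be non-negative and sum to 1")
        if len(self.mixture_variance_scales) != len(self.mixture_proportions):
            raise ValueError("mixture scales and proportions must have equal length")
        if any(s < 0 for s in self.mixture_variance_scales):
            raise ValueError("mixture_variance_scales must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name, v in self.variance_components.items():
            if v < 0:
                raise ValueError(f"variance component {name} must be >= 0")
        for required in ("Va", "Ve"):
            if required not in self.variance_components:
                raise ValueError(f"variance component {required} missing")
        if self.records_per_lactation < 1 or self.n_lactations < 1:
            raise ValueError("records_per_lactation and n_lactations must be >= 1")
        if self.legendre_order < 0:
            raise ValueError("legendre_order must be >= 0")
        if self.dim_window[0] >= self.dim_window[1]:
            raise ValueError("dim_window must be an increasing interval")

    @property
    def effective_n_cdcs(self) -> int:
        if self.n_cdcs is not None:
            return max(1, int(self.n_cdcs))
        return max(1, round(self.n_herds / _HERDS_PER_CDC))


@dataclass
class DefectSpec:
    """Counts of each defect to inject into an otherwise clean simulation.

    Each field maps one-to-one onto a QC filter, so the expected-removal
    manifest produced alongside the corrupted data is exact.
    """

    duplicate_animals: int = 0
    low_call_rate_animals: int = 0
    low_call_rate_snps: int = 0
    monomorphic_snps: int = 0
    sex_mt_snps: int = 0
    outlier_cows: int = 0
    residual_outlier_records: int = 0
    short_lactation_cows: int = 0
    animal_call_rate: float = 0.85     # injected call rate for bad animals
    snp_call_rate: float = 0.90       # injected call rate for bad SNPs

    def total_animal_defects(self) -> int:
        return (
            self.duplicate_animals
            + self.low_call_rate_animals
            + self.outlier_cows
            + self.short_lactation_cows
        )

    def total_snp_defects(self) -> int:
        return self.low_call_rate_snps + self.monomorphic_snps + self.sex_mt_snps


@dataclass
class MCMCConfig:
    """Gibbs-sampler run lengths; defaults are the study's chain settings."""

    n_chains: int = 3
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain: floor((n_iter - burn_in) / thin)."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PhenoQCConfig:
    min_records: int = 4
    dim_window: tuple[int, int] = (8, 340)
    k_sd: float = 3.0
    two_sided: bool = False
    residual_limits: tuple[float, float] = (-2.0, 2.0)
    include_dim_covariates: bool = False
    legendre_order: int = 2


@dataclass
class GenoQCConfig:
    gc_score_threshold: float = 0.15
    duplicate_r_threshold: float = 0.98
    animal_call_rate: float = 0.90
    snp_call_rate: float = 0.95
    maf_threshold: float = 0.01
    autosomes: frozenset = field(default_factory=lambda: frozenset(str(c) for c in range(1, 30)))


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs; defaults are the study thresholds."""

    phenotypes_path: str | None = None
    genotypes_prefix: str | None = None   # PED/MAP prefix
    output_dir: str = "testday_output"
    pheno_qc: PhenoQCConfig = field(default_factory=PhenoQCConfig)
    geno_qc: GenoQCConfig = field(default_factory=GenoQCConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    sim: SimConfig | None = None          # set for synthetic runs
    grm_blend_weight: float = 0.01
    legendre_order: int = 0
    include_pe: bool = False
    include_herd: bool = False
    n_residual_classes: int = 1
    engine: str = "gblup"                 # "gblup" or "bayesr"
    log_level: str = "INFO"

    # -- provenance --------------------------------------------------------
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Output location is excluded so re-running the same analysis into a
        different directory yields identical artifact provenance.
        """
        payload = _to_jsonable(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_to_jsonable(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if kwargs.get("pheno_qc") is not None:
            kwargs["pheno_qc"] = _dataclass_from_dict(PhenoQCConfig, kwargs["pheno_qc"])
        if kwargs.get("geno_qc") is not None:
            d = dict(kwargs["geno_qc"])
            if "autosomes" in d:
                d["autosomes"] = frozenset(str(c) for c in d["autosomes"])
            kwargs["geno_qc"] = _dataclass_from_dict(GenoQCConfig, d)
        if kwargs.get("mcmc") is not None:
            kwargs["mcmc"] = _dataclass_from_dict(MCMCConfig, kwargs["mcmc"])
        if kwargs.get("sim") is not None:
            kwargs["sim"] = _dataclass_from_dict(SimConfig, kwargs["sim"])
        return cls(**kwargs)


def _dataclass_from_dict(cls, raw):
    if isinstance(raw, cls):
        return raw
    names = {f.name for f in fields(cls)}
    clean = {}
    for k, v in raw.items():
        if k not in names:
            raise ValueError(f"unknown {cls.__name__} field {k!r}")
        clean[k] = tuple(v) if isinstance(v, list) else v
    return cls(**clean)


def _to_jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        out = [_to_jsonable(v) for v in obj]
        return sorted(out) if isinstance(obj, (set, frozenset)) else out
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
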