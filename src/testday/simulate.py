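"""Synthetic smallholder dairy populations with known ground truth.

Emulates the data structure of a smallholder crossbred test-day study:
herds of mostly one or two cows grouped under community development centres
(CDCs), monthly fat% records within days 8-340 of lactation, 50K-style
biallelic SNP genotypes in Hardy-Weinberg proportions, and SNP effects drawn
from a BayesR-type four-component normal mixture (one component exactly
zero).  Every generator is deterministic given the configuration seed, and
defects (duplicates, low call rates, outlier cows, ...) are injected *after*
clean simulation together with an exact expected-removal manifest, so QC
filters can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DefectSpec, SimConfig
from .genotypes import GenotypeMatrix
from .legendre import legendre_covariates

__all__ = [
    "GroundTruth",
    "simulate_herds",
    "simulate_genotypes",
    "simulate_snp_effects",
    "simulate_phenotypes",
    "simulate_population",
    "inject_defects",
]

PHENOTYPE_COLUMNS = [
    "animal_id",
    "herd_id",
    "cdc_id",
    "lactation_number",
    "days_in_milk",
    "year_month",
    "fat_pct",
]


@dataclass
class GroundTruth:
    """Latent quantities behind a simulated population, for recovery tests."""

    true_snp_effects: np.ndarray           # fat% per alternate-allele copy
    true_component_assignments: np.ndarray  # mixture class index per SNP
    allele_freqs: np.ndarray               # frequencies used for centering
    true_breeding_values: np.ndarray | None = None   # per animal
    true_fixed_effects: dict = field(default_factory=dict)
    genetic_trajectory_coefs: np.ndarray | None = None  # (n_animals, m) for m > 0

    def breeding_values_from(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """TBV = centered genotypes x true SNP effects, exactly."""
        W = genotypes.calls - 2.0 * self.allele_freqs[None, :]
        return W @ self.true_snp_effects


def _rng(config_or_seed, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    seed = config_or_seed.seed if isinstance(config_or_seed, SimConfig) else config_or_seed
    return np.random.default_rng(seed)


def simulate_herds(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw herd sizes i.i.d. from the configured distribution and assign CDCs.

    Returns one row per animal with columns ``animal_id``, ``herd_id``,
    ``cdc_id``.  Herds are dealt round-robin to ``effective_n_cdcs`` centres,
    which mirrors the roughly even administrative grouping of farms.
    """
    rng = _rng(config, rng)
    dist = np.asarray(config.herd_size_distribution, dtype=float)
    sizes = rng.choice(np.arange(1, dist.size + 1), size=config.n_herds, p=dist)
    n_cdcs = config.effective_n_cdcs
    rows = []
    animal = 0
    for h, size in enumerate(sizes):
        herd_id = f"H{h:05d}"
        cdc_id = f"CDC{h % n_cdcs:03d}"
        for _ in range(int(size)):
            rows.append((f"A{animal:06d}", herd_id, cdc_id))
            animal += 1
    return pd.DataFrame(rows, columns=["animal_id", "herd_id", "cdc_id"])


def simulate_genotypes(
    config: SimConfig, n_animals: int, rng: np.random.Generator | None = None,
    animal_ids: list[str] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy-Weinberg genotypes at per-SNP frequencies uniform on maf_range.

    Chromosome labels cycle over autosomes 1-29; no missingness (defects are
    injected separately).  Returns the matrix and the drawn frequencies.
    """
    if n_animals < 1 or config.n_snps < 1:
        raise ValueError("n_animals and n_snps must be >= 1")
    rng = _rng(config, rng)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    calls = rng.binomial(2, freqs[None, :], size=(n_animals, config.n_snps)).astype(float)
    if animal_ids is None:
        animal_ids = [f"A{i:06d}" for i in range(n_animals)]
    chrom = np.array([str(1 + j % 29) for j in range(config.n_snps)])
    pos = np.arange(1, config.n_snps + 1, dtype=np.int64) * 10_000
    matrix = GenotypeMatrix(
        animal_ids=list(animal_ids),
        snp_ids=[f"SNP{j:06d}" for j in range(config.n_snps)],
        calls=calls,
        chromosome=chrom,
        position_bp=pos,
    )
    return matrix, freqs


def genic_variance_normalizer(config: SimConfig, allele_freqs: np.ndarray) -> float:
    """Scaling that makes the expected total genetic variance equal Va.

    Effects in class k have variance scale_k * Va / normalizer with
    normalizer = mean mixture scale x sum_j 2 p_j (1 - p_j), so that
    Var(sum_j w_j beta_j) ~= Va under Hardy-Weinberg.
    """
    mean_scale = float(
        np.dot(config.mixture_proportions, config.mixture_variance_scales)
    )
    sum_2pq = float(np.sum(2.0 * allele_freqs * (1.0 - allele_freqs)))
    return mean_scale * sum_2pq


def simulate_snp_effects(
    config: SimConfig,
    n_snps: int | None = None,
    allele_freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Assign each SNP a mixture class and draw its additive effect.

    Class 1 has scale exactly 0, so its effects are exactly zero.  Effect
    variances are fractions of the total genic variance (Va) so the implied
    breeding-value variance matches the configured additive variance.
    """
    rng = _rng(config, rng)
    n_snps = config.n_snps if n_snps is None else n_snps
    if allele_freqs is None:
        lo, hi = config.maf_range
        allele_freqs = rng.uniform(lo, hi, size=n_snps)
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if allele_freqs.shape != (n_snps,):
        raise ValueError("allele_freqs length must equal n_snps")
    props = np.asarray(config.mixture_proportions, dtype=float)
    scales = np.asarray(config.mixture_variance_scales, dtype=float)
    classes = rng.choice(props.size, size=n_snps, p=props)
    va = config.variance_components["Va"]
    norm = genic_variance_normalizer(config, allele_freqs)
    effects = np.zeros(n_snps)
    if norm > 0:
        sd = np.sqrt(scales[classes] * va / norm)
        effects = rng.standard_normal(n_snps) * sd
        if config.standardize_genic_variance:
            # rescale so the realized genic variance equals Va exactly; with
            # a sparse mixture few large-effect SNPs dominate and the raw
            # realized variance has a large coefficient of variation
            realized = float(
                np.sum(2.0 * allele_freqs * (1.0 - allele_freqs) * effects**2)
            )
            if realized > 0:
                effects *= np.sqrt(va / realized)
    return GroundTruth(
        true_snp_effects=effects,
        true_component_assignments=classes,
        allele_freqs=allele_freqs,
    )


def _year_month_token(month_index: int) -> str:
    year, month = divmod(month_index, 12)
    return f"{2016 + year:04d}-{month + 1:02d}"


def simulate_phenotypes(
    config: SimConfig,
    herds: pd.DataFrame,
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Test-day fat% records: fixed effects + genetic value + PE + herd + noise.

    Test days are equally spaced within the DIM window (uniform jitter
    optional); the year-month token advances monthly from a per-lactation
    calving month.  The genetic value is the animal's TBV, optionally shaped
    along DIM by higher-order Legendre terms when ``legendre_order > 0``.
    """
    if len(herds) != genotypes.n_animals:
        raise ValueError("herd table and genotype matrix disagree on animal count")
    vc = config.variance_components
    for required in ("Va", "Ve"):
        if required not in vc:
            raise ValueError(f"variance component {required} missing")
    rng = _rng(config, rng)

    tbv = truth.true_breeding_values
    if tbv is None:
        tbv = truth.breeding_values_from(genotypes)
        truth.true_breeding_values = tbv

    n_animals = genotypes.n_animals
    vpe = vc.get("Vpe", 0.0)
    vherd = vc.get("Vherd", 0.0)
    ve = vc["Ve"]
    pe = rng.standard_normal(n_animals) * np.sqrt(vpe)
    herd_ids = sorted(herds["herd_id"].unique())
    herd_eff = dict(zip(herd_ids, rng.standard_normal(len(herd_ids)) * np.sqrt(vherd)))

    # i.i.d. normal fixed-effect level values (magnitudes are configurable).
    sd_fix = config.fixed_effect_sd
    lact_eff = {
        lac: rng.standard_normal() * sd_fix.get("lactation", 0.0)
        for lac in range(1, config.n_lactations + 1)
    }
    lact_eff[1] = 0.0  # reference level
    cdc_ids = sorted(herds["cdc_id"].unique())
    cdc_eff = dict(zip(cdc_ids, rng.standard_normal(len(cdc_ids)) * sd_fix.get("cdc", 0.0)))
    ym_cdc_eff: dict[tuple[str, str], float] = {}

    m = config.legendre_order
    traj_coefs = None
    if m > 0:
        # Higher-order genetic trajectory terms: modest variance relative to Va.
        traj_coefs = rng.standard_normal((n_animals, m)) * np.sqrt(0.1 * vc["Va"])
        truth.genetic_trajectory_coefs = traj_coefs

    lo, hi = config.dim_window
    base_days = np.linspace(lo, hi, config.records_per_lactation)
    rows = []
    for i, (animal_id, herd_id, cdc_id) in enumerate(
        herds[["animal_id", "herd_id", "cdc_id"]].itertuples(index=False)
    ):
        for lac in range(1, config.n_lactations + 1):
            days = base_days.copy()
            if config.jitter_test_days:
                span = (hi - lo) / max(1, config.records_per_lactation - 1)
                days = days + rng.uniform(-span / 4, span / 4, size=days.size)
                days = np.clip(days, lo, hi)
            days = np.round(days).astype(int)
            calving_month = int(rng.integers(0, 24)) + (lac - 1) * 14
            if m > 0:
                basis = legendre_covariates(days, m, config.dim_window).basis_values
            for r, dim in enumerate(days):
                ym = _year_month_token(calving_month + int(dim) // 30)
                key = (ym, cdc_id)
                if key not in ym_cdc_eff:
                    ym_cdc_eff[key] = rng.standard_normal() * sd_fix.get("year_month", 0.0)
                genetic = tbv[i]
                if m > 0:
                    genetic = tbv[i] + float(basis[r, 1:] @ traj_coefs[i])
                value = (
                    config.base_fat_pct
                    + lact_eff[lac]
                    + cdc_eff[cdc_id]
                    + ym_cdc_eff[key]
                    + genetic
                    + pe[i]
                    + herd_eff[herd_id]
                    + rng.standard_normal() * np.sqrt(ve)
                )
                rows.append((animal_id, herd_id, cdc_id, lac, int(dim), ym, value))

    truth.true_fixed_effects = {
        "base": config.base_fat_pct,
        "lactation": lact_eff,
        "cdc": cdc_eff,
        "year_month_cdc": ym_cdc_eff,
        "permanent_environment": dict(zip(herds["animal_id"], pe)),
        "herd": herd_eff,
    }
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


def simulate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, GroundTruth, pd.DataFrame]:
    """Convenience wrapper: herds -> genotypes -> effects -> phenotypes.

    Returns (records, genotypes, truth, herd table); a single RNG seeded
    from ``config.seed`` drives all four stages, so the whole population is
    reproducible bit-for-bit.
    """
    rng = _rng(config)
    herds = simulate_herds(config, rng)
    genotypes, freqs = simulate_genotypes(
        config, len(herds), rng, animal_ids=list(herds["animal_id"])
    )
    truth = simulate_snp_effects(config, config.n_snps, allele_freqs=freqs, rng=rng)
    truth.true_breeding_values = truth.breeding_values_from(genotypes)
    records = simulate_phenotypes(config, herds, genotypes, truth, rng)
    return records, genotypes, truth, herds


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def inject_defects(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    spec: DefectSpec,
    seed: int = 0,
    min_records: int = 4,
) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """Corrupt copies of a clean simulation and return an exact removal manifest.

    The manifest maps each QC filter to the entities it must remove:
    ``duplicates`` (added animal ids), ``animal_call_rate``, ``snp_call_rate``
    / ``monomorphic`` (dropped with the SNP-quality filter), ``non_autosomal``,
    ``outlier_cows``, ``residual_outliers`` (record index labels) and
    ``short_lactation`` (animal ids dropped by the minimum-record filter).
    Defect categories use disjoint entities so expectations compose.
    """
    rng = np.random.default_rng(seed)
    records = records.copy()
    genotypes = genotypes.copy()
    manifest: dict[str, list] = {
        "duplicates": [],
        "animal_call_rate": [],
        "snp_call_rate": [],
        "monomorphic": [],
        "non_autosomal": [],
        "outlier_cows": [],
        "residual_outliers": [],
        "short_lactation": [],
    }

    n_animal_defects = spec.total_animal_defects()
    if n_animal_defects > genotypes.n_animals:
        raise ValueError("requested animal defects exceed population size")
    if spec.total_snp_defects() > genotypes.n_snps:
        raise ValueError("requested SNP defects exceed panel size")
    if spec.residual_outlier_records > len(records):
        raise ValueError("requested record defects exceed record count")

    animal_pool = list(rng.permutation(genotypes.animal_ids))
    snp_pool = list(rng.permutation(genotypes.n_snps))

    def take_animals(k):
        taken, rest = animal_pool[:k], animal_pool[k:]
        animal_pool[:] = rest
        return taken

    def take_snps(k):
        taken, rest = snp_pool[:k], snp_pool[k:]
        snp_pool[:] = rest
        return [int(j) for j in taken]

    # low-call-rate animals: mask enough calls to push the rate below target
    n_mask = int(np.ceil((1.0 - spec.animal_call_rate) * genotypes.n_snps))
    for aid in take_animals(spec.low_call_rate_animals):
        i = genotypes.animal_index(aid)
        cols = rng.choice(genotypes.n_snps, size=n_mask, replace=False)
        genotypes.calls[i, cols] = np.nan
        manifest["animal_call_rate"].append(aid)

    n_mask_snp = int(np.ceil((1.0 - spec.snp_call_rate) * genotypes.n_animals))
    for j in take_snps(spec.low_call_rate_snps):
        rows = rng.choice(genotypes.n_animals, size=n_mask_snp, replace=False)
        genotypes.calls[rows, j] = np.nan
        manifest["snp_call_rate"].append(genotypes.snp_ids[j])

    for j in take_snps(spec.monomorphic_snps):
        genotypes.calls[:, j] = 0.0
        manifest["monomorphic"].append(genotypes.snp_ids[j])

    sex_labels = ["X", "Y", "MT"]
    chrom = genotypes.chromosome.copy().astype(object)
    for k, j in enumerate(take_snps(spec.sex_mt_snps)):
        chrom[j] = sex_labels[k % 3]
        manifest["non_autosomal"].append(genotypes.snp_ids[j])
    genotypes.chromosome = np.asarray(chrom, dtype=str)

    # duplicates last, copying the (possibly masked) row: equal call rates
    # plus ids that sort after the originals make the keep-first tie-break
    # retain the original animal, so the manifest is exact
    for orig in take_animals(spec.duplicate_animals):
        dup_id = f"ZDUP-{orig}"
        i = genotypes.animal_index(orig)
        genotypes = GenotypeMatrix(
            animal_ids=genotypes.animal_ids + [dup_id],
            snp_ids=genotypes.snp_ids,
            calls=np.vstack([genotypes.calls, genotypes.calls[i : i + 1]]),
            chromosome=genotypes.chromosome,
            position_bp=genotypes.position_bp,
            gc_score=None
            if genotypes.gc_score is None
            else np.vstack([genotypes.gc_score, genotypes.gc_score[i : i + 1]]),
        )
        manifest["duplicates"].append(dup_id)

    # phenotype defects
    fat_sd = float(records["fat_pct"].std(ddof=1)) if len(records) > 1 else 1.0
    fat_sd = fat_sd if fat_sd > 0 else 1.0
    for aid in take_animals(spec.outlier_cows):
        mask = records["animal_id"] == aid
        records.loc[mask, "fat_pct"] += 8.0 * fat_sd
        manifest["outlier_cows"].append(aid)

    for aid in take_animals(spec.short_lactation_cows):
        mask = records["animal_id"] == aid
        idx = records.index[mask]
        keep = idx[: max(0, min_records - 1)]
        records = records.drop(index=idx.difference(keep))
        manifest["short_lactation"].append(aid)

    if spec.residual_outlier_records:
        eligible = records.index[
            ~records["animal_id"].isin(
                manifest["outlier_cows"] + manifest["short_lactation"]
            )
        ]
        chosen = rng.choice(eligible, size=spec.residual_outlier_records, replace=False)
        for ridx in chosen:
            records.loc[ridx, "fat_pct"] += 6.0 * fat_sd
            manifest["residual_outliers"].append(ridx)

    return records, genotypes, manifest
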