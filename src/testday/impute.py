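"""Imputation-quality metrics and a mean-dosage baseline imputer.

The headline metric is the squared Pearson correlation between allele
frequencies estimated on two panels (e.g. a medium-density chip and the
high-density panel it is imputed to).  A masking evaluation hides known
calls, re-imputes them and reports concordance of rounded dosages plus
per-SNP dosage r-squared.  The baseline imputer fills missing calls with the
SNP's mean observed dosage; haplotype-based imputation itself is outside the
scope of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix

__all__ = [
    "FrequencyPair",
    "allele_freq_r2",
    "mean_imputer",
    "MeanDosageImputer",
    "masking_concordance",
]


@dataclass(frozen=True)
class FrequencyPair:
    """Allele frequencies for the same SNPs on two panels."""

    snp_ids: tuple[str, ...]
    freq_low_density: np.ndarray
    freq_high_density: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.freq_low_density, dtype=float)
        b = np.asarray(self.freq_high_density, dtype=float)
        if a.shape != b.shape or a.ndim != 1 or len(self.snp_ids) != a.size:
            raise ValueError("frequency vectors and snp_ids must have equal lengths")
        for v in (a, b):
            if (v < 0).any() or (v > 1).any():
                raise ValueError("allele frequencies must lie in [0, 1]")
        object.__setattr__(self, "freq_low_density", a)
        object.__setattr__(self, "freq_high_density", b)


def allele_freq_r2(pair: FrequencyPair) -> float:
    """Squared Pearson correlation of the two frequency vectors."""
    a, b = pair.freq_low_density, pair.freq_high_density
    if a.size < 3:
        raise ValueError("need at least 3 shared SNPs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant frequency vector")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def mean_imputer(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the SNP's mean observed dosage (real-valued).

    Preserves each SNP's observed allele frequency exactly.  Raises if any
    SNP has no observed call.
    """
    out = matrix.copy()
    n_obs = (~np.isnan(out.calls)).sum(axis=0)
    if (n_obs == 0).any():
        bad = [out.snp_ids[j] for j in np.flatnonzero(n_obs == 0)[:10]]
        raise ValueError(f"SNPs with no observed calls cannot be imputed: {bad}")
    col_means = np.nanmean(out.calls, axis=0)
    out.calls = np.where(np.isnan(out.calls), col_means[None, :], out.calls)
    # dosages are real-valued after imputation; bypass the 0/1/2 validation
    return _as_dosage(out)


def _as_dosage(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Build a GenotypeMatrix carrying real-valued dosages (skips 0/1/2 check)."""
    obj = object.__new__(GenotypeMatrix)
    obj.animal_ids = list(matrix.animal_ids)
    obj.snp_ids = list(matrix.snp_ids)
    obj.calls = np.asarray(matrix.calls, dtype=float)
    obj.chromosome = np.asarray(matrix.chromosome, dtype=str)
    obj.position_bp = np.asarray(matrix.position_bp, dtype=np.int64)
    obj.gc_score = matrix.gc_score
    return obj


class MeanDosageImputer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: per-SNP mean-dosage imputation.

    ``fit`` learns the column means from observed calls; ``transform`` fills
    missing entries.  Operates on raw dosage arrays or GenotypeMatrix.
    """

    def fit(self, X, y=None):
        calls = X.calls if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
        n_obs = (~np.isnan(calls)).sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("cannot fit on SNPs with no observed calls")
        self.col_means_ = np.nanmean(calls, axis=0)
        self.n_features_in_ = calls.shape[1]
        return self

    def transform(self, X):
        if isinstance(X, GenotypeMatrix):
            out = _as_dosage(X)
            out.calls = np.where(np.isnan(out.calls), self.col_means_[None, :], out.calls)
            return out
        calls = np.asarray(X, dtype=float)
        return np.where(np.isnan(calls), self.col_means_[None, :], calls)


def _round_dosage(x: np.ndarray) -> np.ndarray:
    """Round to the nearest genotype class; ties round half away from zero."""
    return np.clip(np.floor(x + 0.5), 0, 2)


def masking_concordance(
    matrix: GenotypeMatrix,
    mask_fraction: float,
    imputer=None,
    seed: int = 0,
    max_retries: int = 10,
) -> dict:
    """Hide a random fraction of observed calls, re-impute, and score.

    ``imputer`` is a callable GenotypeMatrix -> GenotypeMatrix (default: the
    mean-dosage baseline).  Returns overall concordance of rounded dosages,
    per-SNP dosage r-squared (nan where the hidden truth is constant), and
    the number of masked calls.  Masks that would leave a SNP with no
    observed call are redrawn (bounded retries).
    """
    if not (0.0 < mask_fraction < 1.0):
        raise ValueError("mask_fraction must lie strictly between 0 and 1")
    imputer = mean_imputer if imputer is None else imputer
    rng = np.random.default_rng(seed)
    observed = np.argwhere(~np.isnan(matrix.calls))
    n_mask = max(1, int(round(mask_fraction * observed.shape[0])))
    for attempt in range(max_retries):
        chosen = observed[rng.choice(observed.shape[0], size=n_mask, replace=False)]
        masked = matrix.copy()
        masked.calls[chosen[:, 0], chosen[:, 1]] = np.nan
        if (~np.isnan(masked.calls)).sum(axis=0).min() > 0:
            break
        import logging

        logging.getLogger(__name__).warning(
            "mask left an all-missing SNP; redrawing (attempt %d)", attempt + 1
        )
    else:
        raise RuntimeError("could not draw a mask leaving every SNP observable")

    completed = imputer(masked)
    truth = matrix.calls[chosen[:, 0], chosen[:, 1]]
    imputed = completed.calls[chosen[:, 0], chosen[:, 1]]
    concordance = float(np.mean(_round_dosage(imputed) == truth))

    per_snp_r2 = {}
    for j in np.unique(chosen[:, 1]):
        sel = chosen[:, 1] == j
        t, p = truth[sel], imputed[sel]
        if t.size >= 2 and np.ptp(t) > 0 and np.ptp(p) > 0:
            r = float(np.corrcoef(t, p)[0, 1])
            per_snp_r2[matrix.snp_ids[int(j)]] = r * r
        else:
            per_snp_r2[matrix.snp_ids[int(j)]] = float("nan")
    return {
        "concordance": concordance,
        "per_snp_r2": per_snp_r2,
        "n_masked": int(n_mask),
    }
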