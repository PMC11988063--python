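"""Genotypic quality control for 50K-style SNP panels.

Stages, run in the order the summary-ledger convention lists them:

1. duplicate detection (pairwise genotype correlation > 0.98; within a
   duplicate group the animal with the highest call rate is kept);
2. animal call rate (> 0.90 retained);
3. SNP call rate (> 0.95) and minor allele frequency (> 0.01), reported as
   one combined drop;
4. restriction to autosomes (chromosomes 1-29 for cattle).

All "higher than" thresholds are strict inequalities for retention.  A
GenCall-score screen (calls with score <= 0.15 set to missing) can precede
the stages when per-call scores are available.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .config import GenoQCConfig
from .genotypes import BOVINE_AUTOSOMES, GenotypeMatrix
from .ledger import QCLedger, QCLedgerEntry

__all__ = [
    "apply_gc_score",
    "detect_duplicates",
    "filter_animal_call_rate",
    "filter_snp_quality",
    "filter_autosomes",
    "run_geno_qc",
    "GenotypeQC",
]

logger = logging.getLogger(__name__)


def apply_gc_score(matrix: GenotypeMatrix, threshold: float = 0.15) -> GenotypeMatrix:
    """Set calls whose GenCall score is <= threshold to missing.

    A no-op (with a logged warning) when the matrix carries no scores, as is
    the case for already-curated exports.
    """
    out = matrix.copy()
    if out.gc_score is None:
        logger.warning("no GenCall scores present; GC-score screen skipped")
        return out
    low = out.gc_score <= threshold
    out.calls[low] = np.nan
    return out


def detect_duplicates(
    matrix: GenotypeMatrix, r_threshold: float = 0.98
) -> tuple[list[tuple[str, str]], GenotypeMatrix, QCLedgerEntry]:
    """Flag animal pairs with genotype correlation above the threshold.

    Correlations are Pearson over the calls both animals have observed.
    Within each connected duplicate group the animal with the highest call
    rate is retained; ties break on animal-id order (first kept).
    """
    n = matrix.n_animals
    if n < 2:
        raise ValueError("duplicate screen needs at least 2 animals")
    calls = matrix.calls
    pairs: list[tuple[str, str]] = []
    drop: set[int] = set()
    call_rates = matrix.animal_call_rate()
    # adjacency of flagged pairs, resolved greedily per group
    flagged: dict[int, set[int]] = {}

    def _flag(i: int, j: int) -> None:
        pairs.append((matrix.animal_ids[i], matrix.animal_ids[j]))
        flagged.setdefault(i, set()).add(j)
        flagged.setdefault(j, set()).add(i)

    if not np.isnan(calls).any():
        sd = calls.std(axis=1)
        ok = sd > 0
        if ok.sum() >= 2:
            sub = np.flatnonzero(ok)
            corr = np.corrcoef(calls[sub])
            ii, jj = np.triu_indices(sub.size, k=1)
            for a, b in zip(ii[corr[ii, jj] > r_threshold], jj[corr[ii, jj] > r_threshold]):
                _flag(int(sub[a]), int(sub[b]))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                shared = ~np.isnan(calls[i]) & ~np.isnan(calls[j])
                if shared.sum() < 2:
                    logger.warning(
                        "animals %s and %s share <2 observed calls; pair skipped",
                        matrix.animal_ids[i], matrix.animal_ids[j],
                    )
                    continue
                xi, xj = calls[i, shared], calls[j, shared]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                if float(np.corrcoef(xi, xj)[0, 1]) > r_threshold:
                    _flag(i, j)
    # union groups, keep best call rate (ties: lowest index, i.e. id order)
    seen: set[int] = set()
    for i in sorted(flagged):
        if i in seen:
            continue
        group = {i}
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for nb in flagged.get(k, ()):
                if nb not in group:
                    group.add(nb)
                    frontier.append(nb)
        seen |= group
        ordered = sorted(group, key=lambda k: (-call_rates[k], matrix.animal_ids[k]))
        drop |= set(ordered[1:])
    keep_idx = [i for i in range(n) if i not in drop]
    entry = QCLedgerEntry(
        stage_name="duplicates",
        threshold=f"genotype r > {r_threshold:g}",
        screened=n,
        retained=len(keep_idx),
        dropped=len(drop),
        unit="animals",
    )
    return pairs, matrix.subset(animal_idx=keep_idx), entry


def filter_animal_call_rate(
    matrix: GenotypeMatrix, threshold: float = 0.90
) -> tuple[GenotypeMatrix, QCLedgerEntry]:
    """Retain animals with call rate strictly above the threshold."""
    rates = matrix.animal_call_rate()
    keep = np.flatnonzero(rates > threshold)
    entry = QCLedgerEntry(
        stage_name="animal_call_rate",
        threshold=f"> {threshold:g}",
        screened=matrix.n_animals,
        retained=keep.size,
        dropped=matrix.n_animals - keep.size,
        unit="animals",
    )
    return matrix.subset(animal_idx=keep), entry


def filter_snp_quality(
    matrix: GenotypeMatrix,
    call_rate_threshold: float = 0.95,
    maf_threshold: float = 0.01,
) -> tuple[GenotypeMatrix, QCLedgerEntry]:
    """Retain SNPs passing both call rate and MAF screens (combined drop).

    Both statistics are recomputed over the currently retained animals, so
    animal-level filtering upstream is reflected here.
    """
    if matrix.n_animals < 1:
        raise ValueError("SNP screen needs at least 1 animal")
    rates = matrix.snp_call_rate()
    maf = matrix.maf()
    keep = np.flatnonzero((rates > call_rate_threshold) & (maf > maf_threshold))
    entry = QCLedgerEntry(
        stage_name="snp_call_rate_and_maf",
        threshold=f"call rate > {call_rate_threshold:g} and MAF > {maf_threshold:g}",
        screened=matrix.n_snps,
        retained=keep.size,
        dropped=matrix.n_snps - keep.size,
        unit="snps",
    )
    return matrix.subset(snp_idx=keep), entry


def filter_autosomes(
    matrix: GenotypeMatrix, autosomes: frozenset[str] = BOVINE_AUTOSOMES
) -> tuple[GenotypeMatrix, QCLedgerEntry]:
    """Drop SNPs on sex chromosomes and the mitochondrion."""
    labels = matrix.chromosome
    recognised = autosomes | {"X", "Y", "MT"}
    unknown = sorted(set(labels) - recognised)
    if unknown:
        raise ValueError(f"unrecognised chromosome labels: {unknown}")
    keep = np.flatnonzero(np.isin(labels, sorted(autosomes)))
    entry = QCLedgerEntry(
        stage_name="autosomes_only",
        threshold="removal of X, Y, MT markers",
        screened=matrix.n_snps,
        retained=keep.size,
        dropped=matrix.n_snps - keep.size,
        unit="snps",
    )
    return matrix.subset(snp_idx=keep), entry


def run_geno_qc(
    matrix: GenotypeMatrix, config: GenoQCConfig | None = None
) -> tuple[GenotypeMatrix, QCLedger]:
    """Run GC-score screen then stages 1-4 in order; emit the cumulative ledger."""
    config = config or GenoQCConfig()
    ledger = QCLedger()
    out = matrix
    if out.gc_score is not None:
        out = apply_gc_score(out, config.gc_score_threshold)
    _, out, entry = detect_duplicates(out, config.duplicate_r_threshold)
    ledger.append(entry)
    out, entry = filter_animal_call_rate(out, config.animal_call_rate)
    ledger.append(entry)
    out, entry = filter_snp_quality(out, config.snp_call_rate, config.maf_threshold)
    ledger.append(entry)
    out, entry = filter_autosomes(out, frozenset(str(c) for c in config.autosomes))
    ledger.append(entry)
    return out, ledger


class GenotypeQC(TransformerMixin, BaseEstimator):
    """Transformer wrapper: ``transform`` filters a GenotypeMatrix in stage order."""

    def __init__(
        self,
        gc_score_threshold: float = 0.15,
        duplicate_r_threshold: float = 0.98,
        animal_call_rate: float = 0.90,
        snp_call_rate: float = 0.95,
        maf_threshold: float = 0.01,
    ):
        self.gc_score_threshold = gc_score_threshold
        self.duplicate_r_threshold = duplicate_r_threshold
        self.animal_call_rate = animal_call_rate
        self.snp_call_rate = snp_call_rate
        self.maf_threshold = maf_threshold

    def fit(self, matrix: GenotypeMatrix, y=None) -> "GenotypeQC":
        if not isinstance(matrix, GenotypeMatrix):
            raise TypeError("GenotypeQC operates on GenotypeMatrix inputs")
        return self

    def transform(self, matrix: GenotypeMatrix) -> GenotypeMatrix:
        cfg = GenoQCConfig(
            gc_score_threshold=self.gc_score_threshold,
            duplicate_r_threshold=self.duplicate_r_threshold,
            animal_call_rate=self.animal_call_rate,
            snp_call_rate=self.snp_call_rate,
            maf_threshold=self.maf_threshold,
        )
        out, ledger = run_geno_qc(matrix, cfg)
        self.ledger_ = ledger
        return out
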