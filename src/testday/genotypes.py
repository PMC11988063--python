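"""In-memory SNP genotype container.

Genotypes are stored as an animals x SNPs float array of alternate-allele
dosages in {0, 1, 2}, with ``nan`` marking missing calls (kept distinct from
the homozygous-reference code 0).  Per-SNP metadata carry the chromosome
label (autosomes ``"1"``..``"29"`` for cattle, plus ``"X"``/``"Y"``/``"MT"``),
base-pair position, and optionally a per-call GenCall-style quality score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "BOVINE_AUTOSOMES"]

BOVINE_AUTOSOMES: frozenset[str] = frozenset(str(c) for c in range(1, 30))


@dataclass
class GenotypeMatrix:
    animal_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray                      # (n_animals, n_snps), float, nan = missing
    chromosome: np.ndarray                 # (n_snps,), str
    position_bp: np.ndarray                # (n_snps,), int
    gc_score: np.ndarray | None = None     # (n_animals, n_snps) in [0, 1], optional

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.chromosome = np.asarray(self.chromosome, dtype=str)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        n, m = self.calls.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match calls rows")
        if len(self.snp_ids) != m or self.chromosome.shape != (m,) or self.position_bp.shape != (m,):
            raise ValueError("SNP metadata length does not match calls columns")
        if self.gc_score is not None:
            self.gc_score = np.asarray(self.gc_score, dtype=float)
            if self.gc_score.shape != self.calls.shape:
                raise ValueError("gc_score shape does not match calls")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype calls must be 0/1/2 or nan")

    # -- shape -------------------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    # -- per-unit statistics ----------------------------------------------
    def animal_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per animal."""
        return 1.0 - np.isnan(self.calls).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    # -- subsetting --------------------------------------------------------
    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        si = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in ai],
            snp_ids=[self.snp_ids[j] for j in si],
            calls=self.calls[np.ix_(ai, si)].copy(),
            chromosome=self.chromosome[si].copy(),
            position_bp=self.position_bp[si].copy(),
            gc_score=None if self.gc_score is None else self.gc_score[np.ix_(ai, si)].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()

    def animal_index(self, animal_id: str) -> int:
        return self.animal_ids.index(animal_id)
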