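"""Genomic relationship matrix (VanRaden) and its numerical stabilization.

Method 1: with per-SNP alternate-allele frequencies p_j, center the dosage
matrix W = M - 2p and form G = W W' / (2 sum_j p_j (1 - p_j)).  Method 2
(per-SNP scaling of the centered columns by 1/sqrt(2 p_j (1 - p_j)), then
G = W* W*' / m) is available by flag.  G is a Gram matrix and therefore
positive semi-definite; duplicated genotypes make it singular, so a small
identity blend (1 - w) G + w I is provided for downstream solvers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix

__all__ = ["GRMatrix", "vanraden_grm", "stabilize", "VanRadenGRM"]


@dataclass
class GRMatrix:
    animal_ids: list[str]
    values: np.ndarray            # (n, n) symmetric
    allele_freqs: np.ndarray      # per-SNP frequencies used for centering

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.animal_ids)
        if self.values.shape != (n, n):
            raise ValueError("G dimensions do not match animal count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("G is not symmetric")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.animal_ids, columns=self.animal_ids)

    def subset(self, animal_ids: list[str]) -> "GRMatrix":
        idx = [self.animal_ids.index(a) for a in animal_ids]
        return GRMatrix(
            animal_ids=list(animal_ids),
            values=self.values[np.ix_(idx, idx)].copy(),
            allele_freqs=self.allele_freqs,
        )


def vanraden_grm(
    matrix: GenotypeMatrix,
    allele_freqs: np.ndarray | None = None,
    method: int = 1,
) -> GRMatrix:
    """Construct G from QC-passed genotypes.

    Missing calls are mean-imputed per SNP before centering (QC caps
    missingness, so the approximation is mild).  Frequencies are computed
    from the data unless supplied.  Monomorphic SNPs make the scaling
    degenerate and are a QC escape, so they raise.
    """
    calls = matrix.calls
    if np.isnan(calls).any():
        col_means = np.nanmean(calls, axis=0)
        calls = np.where(np.isnan(calls), col_means[None, :], calls)
    p = np.asarray(
        allele_freqs if allele_freqs is not None else calls.mean(axis=0) / 2.0,
        dtype=float,
    )
    if p.shape != (matrix.n_snps,):
        raise ValueError("allele_freqs length must equal the SNP count")
    if ((p <= 0) | (p >= 1)).any():
        bad = [matrix.snp_ids[j] for j in np.flatnonzero((p <= 0) | (p >= 1))[:10]]
        raise ValueError(f"monomorphic SNPs present (QC should remove them): {bad}")
    W = calls - 2.0 * p[None, :]
    if method == 1:
        denom = 2.0 * float(np.sum(p * (1.0 - p)))
        G = (W @ W.T) / denom
    elif method == 2:
        Ws = W / np.sqrt(2.0 * p * (1.0 - p))[None, :]
        G = (Ws @ Ws.T) / matrix.n_snps
    else:
        raise ValueError("method must be 1 or 2")
    G = (G + G.T) / 2.0  # kill round-off asymmetry
    return GRMatrix(animal_ids=list(matrix.animal_ids), values=G, allele_freqs=p)


def stabilize(G: GRMatrix, blend_weight: float = 0.01) -> GRMatrix:
    """Blend toward the identity, G* = (1 - w) G + w I, and verify PD.

    Raises with the smallest eigenvalue if the blend is still not positive
    definite (w = 0 on an already-PD matrix is the identity transform).
    """
    if not (0.0 <= blend_weight < 1.0):
        raise ValueError("blend_weight must lie in [0, 1)")
    n = G.n_animals
    if blend_weight == 0.0:
        # identity transform; a centered G always has a zero eigenvalue in
        # the direction of the ones vector, so no PD check is meaningful here
        return GRMatrix(
            animal_ids=list(G.animal_ids),
            values=G.values.copy(),
            allele_freqs=G.allele_freqs,
        )
    values = (1.0 - blend_weight) * G.values + blend_weight * np.eye(n)
    try:
        np.linalg.cholesky(values)
    except np.linalg.LinAlgError:
        smallest = float(np.linalg.eigvalsh(values)[0])
        raise np.linalg.LinAlgError(
            f"stabilized G is not positive definite (smallest eigenvalue {smallest:.3e}); "
            f"increase blend_weight"
        ) from None
    return GRMatrix(animal_ids=list(G.animal_ids), values=values, allele_freqs=G.allele_freqs)


class VanRadenGRM(TransformerMixin, BaseEstimator):
    """Transformer: GenotypeMatrix -> stabilized GRMatrix."""

    def __init__(self, method: int = 1, blend_weight: float = 0.01):
        self.method = method
        self.blend_weight = blend_weight

    def fit(self, matrix: GenotypeMatrix, y=None):
        return self

    def transform(self, matrix: GenotypeMatrix) -> GRMatrix:
        G = vanraden_grm(matrix, method=self.method)
        self.raw_grm_ = G
        return stabilize(G, self.blend_weight) if self.blend_weight > 0 else G
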