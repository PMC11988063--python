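"""Normalized Legendre covariates for random-regression test-day models.

Days in milk t within the recording window [t_min, t_max] are mapped to
x = 2 (t - t_min) / (t_max - t_min) - 1 in [-1, 1], and the basis functions
are phi_k(x) = sqrt((2k + 1) / 2) * P_k(x) with P_k the ordinary Legendre
polynomial, the standard normalization in test-day models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre

__all__ = ["LegendreBasis", "legendre_covariates"]


@dataclass(frozen=True)
class LegendreBasis:
    order: int
    dim_window: tuple[int, int]
    basis_values: np.ndarray   # (n_records, order + 1)

    @property
    def n_coefficients(self) -> int:
        return self.order + 1


def legendre_covariates(dim_values, order: int, dim_window=(8, 340)) -> LegendreBasis:
    """Evaluate phi_0..phi_order at each days-in-milk value.

    Raises if any DIM falls outside the closed window (such records should
    have been removed by phenotypic QC).
    """
    t = np.asarray(dim_values, dtype=float)
    t_min, t_max = float(dim_window[0]), float(dim_window[1])
    if order < 0:
        raise ValueError("order must be >= 0")
    if t_min >= t_max:
        raise ValueError("dim_window must be an increasing interval")
    out_of_window = (t < t_min) | (t > t_max)
    if out_of_window.any():
        bad = np.unique(t[out_of_window])
        raise ValueError(f"DIM values outside window [{t_min:g}, {t_max:g}]: {bad[:10]}")
    x = 2.0 * (t - t_min) / (t_max - t_min) - 1.0
    ks = np.arange(order + 1)
    scale = np.sqrt((2.0 * ks + 1.0) / 2.0)
    basis = scale[None, :] * eval_legendre(ks[None, :], x[:, None])
    return LegendreBasis(order=order, dim_window=(dim_window[0], dim_window[1]), basis_values=basis)
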