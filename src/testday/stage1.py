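"""Stage 1: repeatability animal model and adjusted test-day records.

The model is y = Xb + Z1 a + Z2 h + e with fixed effects b (lactation
number, CDC, year-month x CDC), random animal effects a ~ N(0, sigma2_a I)
and random herd effects h ~ N(0, sigma2_h I) — animals are deliberately
treated as unrelated at this stage — and residuals e ~ N(0, sigma2_e I).
Variance components are estimated by EM-REML on Henderson's mixed-model
equations; solving the MME at the estimates yields BLUE(b), BLUP(a),
BLUP(h).  The adjusted record is y - Xb_hat = a_hat + h_hat + e_hat,
reported per record as the components IFE (record-level residual), ARE
(animal effect) and HRE (herd effect) with AFP = IFE + ARE + HRE.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from sklearn.base import BaseEstimator

__all__ = [
    "Stage1Design",
    "Stage1Fit",
    "build_design",
    "estimate_variances_em_reml",
    "solve_mme",
    "adjust_records",
    "RepeatabilityModel",
]

logger = logging.getLogger(__name__)


@dataclass
class Stage1Design:
    y: np.ndarray                 # (n,)
    X: np.ndarray                 # (n, p) full column rank
    Z1: np.ndarray                # (n, n_animals) incidence
    Z2: np.ndarray                # (n, n_herds) incidence
    animal_ids: list[str]
    herd_ids: list[str]
    fixed_names: list[str]
    record_index: np.ndarray = field(default=None)

    @property
    def n_records(self) -> int:
        return self.y.size


@dataclass
class Stage1Fit:
    b_hat: np.ndarray
    a_hat: np.ndarray
    h_hat: np.ndarray
    e_hat: np.ndarray
    variance_components: dict
    design: Stage1Design


def _drop_first_dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series.astype(str), prefix=prefix, drop_first=True, dtype=float)
    return d


def build_design(records: pd.DataFrame) -> Stage1Design:
    """Incidence matrices for the repeatability model.

    Fixed effects use reference-level (drop-first) coding with an intercept;
    columns made linearly dependent by confounding (common for sparse
    year-month x CDC cells) are absorbed automatically via QR column
    selection, with a warning naming how many were dropped.
    """
    required = ("animal_id", "herd_id", "cdc_id", "lactation_number", "year_month", "fat_pct")
    for col in required:
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
        if records[col].isna().any():
            bad = records.index[records[col].isna()][0]
            raise ValueError(f"record {bad!r} has a missing {col!r} level")
    y = records["fat_pct"].to_numpy(dtype=float)

    blocks = [pd.DataFrame({"intercept": np.ones(len(records))}, index=records.index)]
    blocks.append(_drop_first_dummies(records["lactation_number"], "lact"))
    blocks.append(_drop_first_dummies(records["cdc_id"], "cdc"))
    inter = records["year_month"].astype(str) + ":" + records["cdc_id"].astype(str)
    blocks.append(_drop_first_dummies(inter, "ym_cdc"))
    Xdf = pd.concat(blocks, axis=1)
    X = Xdf.to_numpy(dtype=float)
    names = list(Xdf.columns)

    # full-rank check via pivoted QR; absorb dependent columns
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = X.shape[1] - rank
        warnings.warn(
            f"fixed-effect design rank-deficient; absorbed {dropped} confounded column(s)",
            stacklevel=2,
        )
        X = X[:, keep]
        names = [names[k] for k in keep]

    animal_ids = sorted(records["animal_id"].unique())
    herd_ids = sorted(records["herd_id"].unique())
    a_index = {a: k for k, a in enumerate(animal_ids)}
    h_index = {h: k for k, h in enumerate(herd_ids)}
    n = len(records)
    Z1 = np.zeros((n, len(animal_ids)))
    Z2 = np.zeros((n, len(herd_ids)))
    rows = np.arange(n)
    Z1[rows, records["animal_id"].map(a_index).to_numpy()] = 1.0
    Z2[rows, records["herd_id"].map(h_index).to_numpy()] = 1.0
    return Stage1Design(
        y=y, X=X, Z1=Z1, Z2=Z2,
        animal_ids=animal_ids, herd_ids=herd_ids, fixed_names=names,
        record_index=records.index.to_numpy(),
    )


def _mme_blocks(design: Stage1Design):
    W = np.hstack([design.X, design.Z1, design.Z2])
    return W, W.T @ W, W.T @ design.y


def _solve_coefficient_system(WtW, Wty, p, na, nh, lam_a, lam_h):
    C = WtW.copy()
    idx_a = slice(p, p + na)
    idx_h = slice(p + na, p + na + nh)
    C[idx_a, idx_a] += np.eye(na) * lam_a
    C[idx_h, idx_h] += np.eye(nh) * lam_h
    try:
        cf = sla.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular mixed-model coefficient matrix; consider merging confounded "
            "fixed-effect levels"
        ) from err
    sol = sla.cho_solve(cf, Wty, check_finite=False)
    return C, cf, sol, idx_a, idx_h


def _em_step(state, pre, na, nh, n, p, floor):
    """One EM-REML update from Henderson's MME, via the absorbed system.

    With the fixed-effect block absorbed once (Schur complement), only the
    (na + nh)-dimensional random-effect system is factorized per step; its
    inverse is exactly the random-effect block of the full MME inverse, so
    the classic updates sigma2_u = (u'u + sigma2_e tr(C^uu)) / q_u and
    sigma2_e = y'(y - W s) / (n - p) are unchanged.
    """
    lam_a = state["sigma2_e"] / max(state["sigma2_a"], floor)
    S = pre["S0"].copy()
    S[: na, : na] += np.eye(na) * lam_a
    if nh > 0:
        lam_h = state["sigma2_e"] / max(state["sigma2_h"], floor)
        S[na :, na :] += np.eye(nh) * lam_h
    try:
        cf = sla.cho_factor(S, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular mixed-model coefficient matrix; consider merging confounded "
            "fixed-effect levels"
        ) from err
    u = sla.cho_solve(cf, pre["rhs_z"], check_finite=False)
    Sinv = sla.cho_solve(cf, np.eye(na + nh), check_finite=False)
    a_hat, h_hat = u[:na], u[na:]
    b_hat = pre["CxxinvXty"] - pre["CxxinvCxz"] @ u
    fit_dot = float(b_hat @ pre["Xty"]) + float(u @ pre["Zty"])
    new_e = (pre["yty"] - fit_dot) / (n - p)
    new_a = (float(a_hat @ a_hat) + new_e * float(np.trace(Sinv[:na, :na]))) / na
    new_h = (
        (float(h_hat @ h_hat) + new_e * float(np.trace(Sinv[na:, na:]))) / nh
        if nh > 0
        else 0.0
    )
    return {
        "sigma2_a": max(new_a, floor),
        "sigma2_h": max(new_h, floor),
        "sigma2_e": max(new_e, floor),
    }


def estimate_variances_em_reml(
    design: Stage1Design,
    tolerance: float = 1e-5,
    max_iter: int = 1000,
    start: dict | None = None,
    accelerate: bool = True,
) -> dict:
    """EM-REML for (sigma2_a, sigma2_h, sigma2_e) via Henderson's MME.

    Classic EM updates: sigma2_u = (u_hat' u_hat + sigma2_e tr(C^uu)) / q_u
    for each random factor and sigma2_e = y'(y - W s_hat) / (n - rank(X)).
    The fixed-effect block is absorbed once so each iteration only
    factorizes the random-effect system, and the geometric EM trajectory is
    Aitken-extrapolated (a standard acceleration that shares the EM fixed
    point) — single-cow herds confound animal and herd effects, which makes
    plain EM crawl along the resulting likelihood ridge.  Components are
    floored at a tiny positive fraction of var(y); convergence is declared
    when every component's relative change drops below tolerance.  Raises on
    non-convergence, carrying the iteration trajectory.
    """
    y = design.y
    n, p = design.X.shape
    na, nh = design.Z1.shape[1], design.Z2.shape[1]
    if na < 2:
        raise ValueError("EM-REML needs at least 2 animals")
    vy = float(np.var(y)) or 1.0
    floor = 1e-8 * vy
    state = dict(start or {"sigma2_a": 0.2 * vy, "sigma2_h": 0.1 * vy, "sigma2_e": 0.7 * vy})

    X, Z = design.X, np.hstack([design.Z1, design.Z2])
    Xty, Zty = X.T @ y, Z.T @ y
    Cxx = X.T @ X
    Cxz = X.T @ Z
    cfx = sla.cho_factor(Cxx, lower=True, check_finite=False)
    CxxinvCxz = sla.cho_solve(cfx, Cxz, check_finite=False)
    pre = {
        "S0": Z.T @ Z - Cxz.T @ CxxinvCxz,
        "rhs_z": Zty - CxxinvCxz.T @ Xty,
        "CxxinvXty": sla.cho_solve(cfx, Xty, check_finite=False),
        "CxxinvCxz": CxxinvCxz,
        "Xty": Xty,
        "Zty": Zty,
        "yty": float(y @ y),
    }

    keys = ("sigma2_a", "sigma2_h", "sigma2_e")
    # components below ~0.1% of var(y) are effectively at the boundary; use
    # that scale as the convergence denominator so they cannot stall the test
    denom_floor = 1e-3 * vy
    trajectory = []
    prev_delta = None
    for it in range(max_iter):
        new = _em_step(state, pre, na, nh, n, p, floor)
        delta = np.array([new[k] - state[k] for k in keys])
        rel = max(
            abs(new[k] - state[k]) / max(state[k], denom_floor) for k in keys
        )
        trajectory.append(dict(new))
        state = new
        if rel < tolerance:
            state["n_iter"] = it + 1
            return state
        # component-wise Aitken extrapolation of the (near-geometric) EM
        # trajectory; jumps are capped so ratio estimates near 1 cannot
        # overshoot wildly, and the floor keeps components positive
        if accelerate and prev_delta is not None and it % 3 == 2:
            new_state = dict(state)
            for k, d, d_prev in zip(keys, delta, prev_delta):
                if d_prev == 0.0 or d == 0.0:
                    continue
                r = d / d_prev
                if 1e-3 < r < 1.0:
                    jump = min(r / (1.0 - r), 1000.0)
                    new_state[k] = max(state[k] + jump * d, floor)
            state = new_state
            delta = None  # restart the geometric-ratio estimate
        prev_delta = delta
    raise RuntimeError(
        f"EM-REML did not converge in {max_iter} iterations; trajectory tail: "
        f"{trajectory[-3:]}"
    )


def solve_mme(design: Stage1Design, variance_components: dict) -> Stage1Fit:
    """BLUE/BLUP solutions of the MME at given variance components."""
    s2e = variance_components["sigma2_e"]
    if s2e <= 0:
        raise ValueError("sigma2_e must be positive")
    s2a = max(variance_components["sigma2_a"], 0.0)
    s2h = max(variance_components["sigma2_h"], 0.0)
    n, p = design.X.shape
    na, nh = design.Z1.shape[1], design.Z2.shape[1]
    # zero variance => infinite shrinkage; implement with a huge ridge
    big = 1e12
    lam_a = s2e / s2a if s2a > 0 else big
    lam_h = s2e / s2h if s2h > 0 else big
    _, WtW, Wty = _mme_blocks(design)
    _, _, sol, idx_a, idx_h = _solve_coefficient_system(WtW, Wty, p, na, nh, lam_a, lam_h)
    b_hat = sol[:p]
    a_hat = sol[idx_a]
    h_hat = sol[idx_h]
    e_hat = design.y - design.X @ b_hat - design.Z1 @ a_hat - design.Z2 @ h_hat
    return Stage1Fit(
        b_hat=b_hat, a_hat=a_hat, h_hat=h_hat, e_hat=e_hat,
        variance_components={"sigma2_a": s2a, "sigma2_h": s2h, "sigma2_e": s2e},
        design=design,
    )


def adjust_records(fit: Stage1Fit, records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-record adjusted fat%: AFP = IFE + ARE + HRE = y - X b_hat.

    IFE is the record-level residual e_hat, ARE the animal BLUP, HRE the
    herd BLUP.  Additivity is exact by construction.
    """
    design = fit.design
    a_of_record = design.Z1 @ fit.a_hat
    h_of_record = design.Z2 @ fit.h_hat
    animal_col = np.array(design.animal_ids)[design.Z1.argmax(axis=1)]
    out = pd.DataFrame(
        {
            "animal_id": animal_col,
            "ife": fit.e_hat,
            "are": a_of_record,
            "hre": h_of_record,
        },
        index=design.record_index,
    )
    out["afp"] = out["ife"] + out["are"] + out["hre"]
    if records is not None:
        for col in ("herd_id", "cdc_id", "lactation_number", "days_in_milk", "year_month"):
            if col in records.columns:
                out[col] = records.loc[out.index, col]
    return out


class RepeatabilityModel(BaseEstimator):
    """Sklearn-style estimator for the stage-1 repeatability animal model.

    ``fit`` takes the test-day record table, estimates variance components
    by EM-REML (unless all three are supplied) and solves the MME.  Fitted
    attributes: ``sigma2_a_``, ``sigma2_h_``, ``sigma2_e_``, ``b_``, ``a_``
    (Series by animal), ``h_`` (Series by herd), ``fit_`` (full solution).
    ``adjust()`` returns the adjusted-record table.
    """

    def __init__(
        self,
        tolerance: float = 1e-5,
        max_iter: int = 1000,
        sigma2_a: float | None = None,
        sigma2_h: float | None = None,
        sigma2_e: float | None = None,
    ):
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.sigma2_a = sigma2_a
        self.sigma2_h = sigma2_h
        self.sigma2_e = sigma2_e

    def fit(self, records: pd.DataFrame, y=None) -> "RepeatabilityModel":
        design = build_design(records)
        given = (self.sigma2_a, self.sigma2_h, self.sigma2_e)
        if all(v is not None for v in given):
            vc = {"sigma2_a": self.sigma2_a, "sigma2_h": self.sigma2_h,
                  "sigma2_e": self.sigma2_e}
        else:
            vc = estimate_variances_em_reml(design, self.tolerance, self.max_iter)
        self.fit_ = solve_mme(design, vc)
        self.design_ = design
        self.sigma2_a_ = self.fit_.variance_components["sigma2_a"]
        self.sigma2_h_ = self.fit_.variance_components["sigma2_h"]
        self.sigma2_e_ = self.fit_.variance_components["sigma2_e"]
        self.b_ = pd.Series(self.fit_.b_hat, index=design.fixed_names)
        self.a_ = pd.Series(self.fit_.a_hat, index=design.animal_ids)
        self.h_ = pd.Series(self.fit_.h_hat, index=design.herd_ids)
        self._records = records
        return self

    def adjust(self, records: pd.DataFrame | None = None) -> pd.DataFrame:
        if not hasattr(self, "fit_"):
            raise RuntimeError("call fit() before adjust()")
        return adjust_records(self.fit_, self._records if records is None else records)
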