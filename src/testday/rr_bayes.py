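"""Stage 2: Bayesian inference for genetic parameters and GEBV.

Two Gibbs-sampling engines share one posterior-summary interface:

* :class:`GBLUPSampler` — the random-regression animal model on adjusted
  records, y* = mu + Z1 a + Z2 p + Z3 h + e, where each animal's additive
  genetic (a) and permanent environmental (p) effects and each herd's
  effect (h) are coefficient vectors on a normalized Legendre basis of
  days in milk.  The covariance structure is var(a) = G (x) Ka with G the
  genomic relationship matrix, var(p) = I (x) Kp, var(h) = I (x) Kh, and a
  diagonal residual covariance homogeneous within and heterogeneous between
  lactation-period (DIM) classes.  Coefficient blocks are drawn from their
  normal full conditionals, the K matrices from inverse-Wishart full
  conditionals, and each residual-class variance from a scaled inverse
  chi-square.  When the model reduces to an intercept-only genetic effect
  (order 0, no PE/herd terms, one residual class) an exact eigendecomposition
  path samples the same full conditionals at a fraction of the cost.

* :class:`BayesRRegressor` — the SNP-mixture engine on one aggregated
  record per genotyped animal: each SNP effect is drawn from a
  four-component normal mixture (variances 0, 1e-4, 1e-3 and 1e-2 times the
  genic variance by default, the first class exactly zero), class
  memberships from the component posterior odds, mixture proportions from a
  Dirichlet, and the genic and residual variances from scaled inverse
  chi-squares.  GEBV = W (posterior-mean effects).

Heritability is defined as h2 = Va / (Va + Ve) on every retained draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .config import MCMCConfig
from .grm import GRMatrix
from .legendre import legendre_covariates

__all__ = [
    "DEFAULT_RESIDUAL_CLASS_EDGES",
    "PosteriorSummary",
    "GBLUPSampler",
    "BayesRRegressor",
    "gibbs_rr_gblup",
    "bayesr_snp_engine",
    "heritability",
    "gebv_from_posterior",
    "gebv_summary",
    "split_rhat",
    "convergence_diagnostics",
]

logger = logging.getLogger(__name__)

#: Default DIM bands for the heterogeneous residual classes (closed on the
#: left, the last closed on both sides): 8-45, 46-115, 116-225, 226-340.
DEFAULT_RESIDUAL_CLASS_EDGES: tuple[int, ...] = (8, 46, 116, 226, 341)


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Retained MCMC draws and derived quantities for one engine run."""

    engine: str
    draws: dict                       # name -> (chains, n_retained[, k, k])
    animal_ids: list[str]
    gebv_mean: np.ndarray             # posterior-mean GEBV per animal
    n_retained_per_chain: int
    config: MCMCConfig
    snp_summaries: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).reshape(-1)

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws[name]))

    def sd(self, name: str) -> float:
        return float(np.std(self.stacked(name), ddof=1))

    @property
    def h2_mean(self) -> float:
        return self.mean("h2")

    @property
    def h2_sd(self) -> float:
        return self.sd("h2")

    def credible_interval(self, name: str, level: float = 0.90) -> tuple[float, float]:
        x = self.stacked(name)
        lo = (1.0 - level) / 2.0
        return (float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo)))

    def gebv_table(self) -> pd.DataFrame:
        out = pd.DataFrame({"animal_id": self.animal_ids, "gebv": self.gebv_mean})
        return out.sort_values("gebv", ascending=False, ignore_index=True)

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if np.asarray(v).ndim == 2]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _sample_scaled_inv_chi2(rng, df: float, scale_sum: float) -> float:
    """Draw from scaled-inv-chi2: scale_sum / chi2(df)."""
    return scale_sum / rng.chisquare(df)


def _sample_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    k = scale.shape[0]
    if k == 1:
        return np.array([[_sample_scaled_inv_chi2(rng, df, float(scale[0, 0]))]])
    return stats.invwishart.rvs(df=df, scale=scale, random_state=rng).reshape(k, k)


def _chain_rngs(config: MCMCConfig) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    return [np.random.default_rng(s) for s in seqs]


def heritability(va: float, ve: float) -> float:
    """h2 = Va / (Va + Ve); herd and PE variances are excluded from the denominator."""
    if va < 0 or ve < 0:
        raise ValueError("variance components must be non-negative")
    if va + ve == 0:
        raise ValueError("h2 undefined when Va + Ve = 0")
    return va / (va + ve)


def _residual_class_index(dim: np.ndarray, edges) -> np.ndarray:
    if edges is None:
        return np.zeros(dim.size, dtype=int)
    edges = np.asarray(edges)
    idx = np.searchsorted(edges, dim, side="right") - 1
    idx = np.clip(idx, 0, edges.size - 2)
    return idx.astype(int)


# ---------------------------------------------------------------------------
# RR-GBLUP Gibbs
# ---------------------------------------------------------------------------

class GBLUPSampler(BaseEstimator):
    """Gibbs sampler for the random-regression GBLUP model.

    Parameters
    ----------
    order : Legendre order m of the genetic/PE/herd trajectories (m + 1
        coefficients per level).  Order 0 is an intercept-only effect.
    include_pe, include_herd : include the permanent-environmental and herd
        regression terms.
    residual_class_edges : DIM band edges for heterogeneous residual
        variances, or None for a single homogeneous class.
    dim_window : closed DIM window for the Legendre mapping.
    prior_k_scale, prior_k_df_add : inverse-Wishart prior for each K is
        IW(dim + prior_k_df_add, prior_k_scale * var(y) * I).
    prior_resid_df, prior_resid_scale : scaled-inv-chi2 prior for each
        residual class variance, scale expressed as a fraction of var(y).
    update_variances : when False, Ka/Kp/Kh/R stay at their initial values
        (used for conjugate-oracle checks against the closed-form BLUP).
    n_gebv_grid : DIM grid size over which genetic trajectories are averaged
        into a single GEBV per animal.

    Fitted attributes: ``posterior_`` (:class:`PosteriorSummary`),
    ``gebv_`` (posterior-mean GEBV aligned with the G animal order).
    """

    def __init__(
        self,
        order: int = 0,
        include_pe: bool = False,
        include_herd: bool = False,
        residual_class_edges=None,
        dim_window: tuple[int, int] = (8, 340),
        mcmc: MCMCConfig | None = None,
        prior_k_scale: float = 0.01,
        prior_k_df_add: int = 2,
        prior_resid_df: float = 4.0,
        prior_resid_scale: float = 0.5,
        init_variances: dict | None = None,
        update_variances: bool = True,
        n_gebv_grid: int = 101,
        force_general: bool = False,
    ):
        self.order = order
        self.include_pe = include_pe
        self.include_herd = include_herd
        self.residual_class_edges = residual_class_edges
        self.dim_window = dim_window
        self.mcmc = mcmc
        self.prior_k_scale = prior_k_scale
        self.prior_k_df_add = prior_k_df_add
        self.prior_resid_df = prior_resid_df
        self.prior_resid_scale = prior_resid_scale
        self.init_variances = init_variances
        self.update_variances = update_variances
        self.n_gebv_grid = n_gebv_grid
        self.force_general = force_general

    # -- public API --------------------------------------------------------
    def fit(self, adjusted: pd.DataFrame, G: GRMatrix) -> "GBLUPSampler":
        """Run all chains on an adjusted-record table.

        ``adjusted`` needs columns ``animal_id``, a response column (``afp``
        preferred, else ``fat_pct``), ``days_in_milk``, and ``herd_id`` when
        the herd term is included.  Animals must all be present in G.
        """
        mcmc = self.mcmc or MCMCConfig()
        ycol = "afp" if "afp" in adjusted.columns else "fat_pct"
        if ycol not in adjusted.columns:
            raise ValueError("adjusted records need an 'afp' or 'fat_pct' column")
        y = adjusted[ycol].to_numpy(dtype=float)
        animals = [a for a in G.animal_ids if a in set(adjusted["animal_id"])]
        if not animals:
            raise ValueError("no adjusted-record animal appears in G")
        skipped = set(adjusted["animal_id"]) - set(G.animal_ids)
        if skipped:
            logger.info("excluding %d animals without genotypes", len(skipped))
            keep = adjusted["animal_id"].isin(set(animals))
            adjusted = adjusted[keep]
            y = adjusted[ycol].to_numpy(dtype=float)
        Gsub = G.subset(animals) if len(animals) != G.n_animals else G
        a_index = {a: i for i, a in enumerate(animals)}
        animal_idx = adjusted["animal_id"].map(a_index).to_numpy()
        dim = adjusted["days_in_milk"].to_numpy(dtype=float)
        herd_idx = None
        herd_ids: list[str] = []
        if self.include_herd:
            if "herd_id" not in adjusted.columns:
                raise ValueError("herd term requested but records lack 'herd_id'")
            herd_ids = sorted(adjusted["herd_id"].unique())
            h_index = {h: i for i, h in enumerate(herd_ids)}
            herd_idx = adjusted["herd_id"].map(h_index).to_numpy()

        self.posterior_ = _run_gblup_chains(
            y=y, animal_idx=animal_idx, dim=dim, herd_idx=herd_idx,
            animal_ids=animals, herd_ids=herd_ids, G=Gsub, mcmc=mcmc, params=self,
        )
        self.gebv_ = self.posterior_.gebv_mean
        self.animal_ids_ = animals
        return self

    def predict(self, animal_ids=None) -> np.ndarray:
        """Posterior-mean GEBV, optionally re-ordered to the given ids."""
        if not hasattr(self, "posterior_"):
            raise RuntimeError("call fit() first")
        if animal_ids is None:
            return self.gebv_
        index = {a: i for i, a in enumerate(self.animal_ids_)}
        return np.array([self.gebv_[index[a]] for a in animal_ids])


def _run_gblup_chains(y, animal_idx, dim, herd_idx, animal_ids, herd_ids, G,
                      mcmc: MCMCConfig, params: GBLUPSampler) -> PosteriorSummary:
    n_records = y.size
    na = len(animal_ids)
    k = params.order + 1
    vy = float(np.var(y)) or 1.0
    edges = params.residual_class_edges
    class_idx = _residual_class_index(dim, edges)
    n_classes = int(class_idx.max()) + 1
    basis = legendre_covariates(dim, params.order, params.dim_window).basis_values

    Ginv = np.linalg.inv(G.values)
    fast = (
        params.order == 0
        and not params.include_pe
        and not params.include_herd
        and n_classes == 1
        and not params.force_general
    )

    grid = np.linspace(params.dim_window[0], params.dim_window[1], params.n_gebv_grid)
    grid_basis = legendre_covariates(grid, params.order, params.dim_window).basis_values
    grid_mean = grid_basis.mean(axis=0)            # (k,)
    #: per-draw genetic variance = average over DIM grid of phi' Ka phi
    grid_quad = grid_basis[:, :, None] * grid_basis[:, None, :]
    grid_quad_mean = grid_quad.mean(axis=0)        # (k, k)

    s0_k = params.prior_k_scale * vy
    nu_k = k + params.prior_k_df_add
    nu_e = params.prior_resid_df
    s_e = params.prior_resid_scale * vy

    init = dict(params.init_variances or {})
    ka0 = init.get("Ka", np.eye(k) * init.get("sigma2_a", 0.1 * vy))
    kp0 = init.get("Kp", np.eye(k) * init.get("sigma2_pe", 0.05 * vy))
    kh0 = init.get("Kh", np.eye(k) * init.get("sigma2_herd", 0.05 * vy))
    r0 = init.get("sigma2_e", 0.8 * vy)
    ka0 = np.atleast_2d(np.asarray(ka0, dtype=float))
    kp0 = np.atleast_2d(np.asarray(kp0, dtype=float))
    kh0 = np.atleast_2d(np.asarray(kh0, dtype=float))

    n_ret = mcmc.n_retained
    store: dict[str, list] = {name: [] for name in ("mu", "Va", "Ve", "Vpe", "Vherd", "h2")}
    ka_draws, resid_draws = [], []
    gebv_accum = np.zeros(na)

    rngs = _chain_rngs(mcmc)
    for rng in rngs:
        if fast:
            out = _gblup_chain_fast(
                y, animal_idx, na, Ginv, mcmc, rng,
                s0_k=s0_k, nu_k=nu_k, nu_e=nu_e, s_e=s_e,
                sigma2_g0=float(ka0[0, 0]) / 2.0,
                sigma2_e0=r0,
                update_variances=params.update_variances,
            )
        else:
            out = _gblup_chain_general(
                y, animal_idx, herd_idx, basis, class_idx, n_classes, na,
                herd_count=len(herd_ids), Ginv=Ginv, mcmc=mcmc, rng=rng,
                params=params, ka0=ka0, kp0=kp0, kh0=kh0, r0=r0,
                s0_k=s0_k, nu_k=nu_k, nu_e=nu_e, s_e=s_e,
                grid_mean=grid_mean, grid_quad_mean=grid_quad_mean,
            )
        for name in store:
            store[name].append(out[name])
        ka_draws.append(out["Ka"])
        resid_draws.append(out["R"])
        gebv_accum += out["gebv_sum"]

    draws = {name: np.asarray(vals) for name, vals in store.items()}
    draws["Ka"] = np.asarray(ka_draws)
    draws["R"] = np.asarray(resid_draws)
    gebv_mean = gebv_accum / (mcmc.n_chains * n_ret)
    return PosteriorSummary(
        engine="gblup",
        draws=draws,
        animal_ids=list(animal_ids),
        gebv_mean=gebv_mean,
        n_retained_per_chain=n_ret,
        config=mcmc,
    )


def _gblup_chain_fast(y, animal_idx, na, Ginv, mcmc, rng, *, s0_k, nu_k,
                      nu_e, s_e, sigma2_g0, sigma2_e0, update_variances):
    """Intercept-only genetic model, single residual class.

    Works in genetic-value space g = phi_0 * a (prior var sigma2_g G with
    sigma2_g = Ka_00 / 2), diagonalizing D^{-1/2} G^{-1} D^{-1/2} once so
    every coefficient draw is O(n^2).  The full conditionals are identical
    to the general path's, only reparameterized.
    """
    n_records = y.size
    counts = np.bincount(animal_idx, minlength=na).astype(float)
    if (counts == 0).any():
        raise ValueError("every animal in G must have at least one record")
    d_half_inv = 1.0 / np.sqrt(counts)
    M = (Ginv * d_half_inv[None, :]) * d_half_inv[:, None]
    lam, V = np.linalg.eigh(M)
    Zt_of = lambda r: np.bincount(animal_idx, weights=r, minlength=na)

    # IW(nu_k, s0_k I) on Ka_00 maps to scale s0_k/2 on sigma2_g = Ka_00/2
    s0_g = s0_k / 2.0

    mu = float(y.mean())
    g = np.zeros(na)
    sigma2_g = float(sigma2_g0)
    sigma2_e = float(sigma2_e0)

    keep = np.zeros(mcmc.n_retained)
    out = {name: keep.copy() for name in ("mu", "Va", "Ve", "Vpe", "Vherd", "h2")}
    ka = np.zeros((mcmc.n_retained, 1, 1))
    rr = np.zeros((mcmc.n_retained, 1))
    gebv_sum = np.zeros(na)
    kept = 0
    for it in range(mcmc.n_iter):
        # g | rest
        rhs = Zt_of(y - mu) / sigma2_e
        b = V.T @ (d_half_inv * rhs)
        dvec = 1.0 / sigma2_e + lam / sigma2_g
        alpha = b / dvec + rng.standard_normal(na) / np.sqrt(dvec)
        g = d_half_inv * (V @ alpha)
        # mu | rest
        resid0 = y - g[animal_idx]
        mu = float(rng.normal(resid0.mean(), np.sqrt(sigma2_e / n_records)))
        e = resid0 - mu
        if update_variances:
            quad = float(g @ (Ginv @ g))
            sigma2_g = _sample_scaled_inv_chi2(rng, nu_k + na, s0_g + quad)
            sigma2_e = _sample_scaled_inv_chi2(
                rng, nu_e + n_records, nu_e * s_e + float(e @ e)
            )
        if it >= mcmc.burn_in and (it + 1 - mcmc.burn_in) % mcmc.thin == 0:
            out["mu"][kept] = mu
            out["Va"][kept] = sigma2_g
            out["Ve"][kept] = sigma2_e
            out["Vpe"][kept] = 0.0
            out["Vherd"][kept] = 0.0
            out["h2"][kept] = heritability(sigma2_g, sigma2_e)
            ka[kept, 0, 0] = 2.0 * sigma2_g
            rr[kept, 0] = sigma2_e
            gebv_sum += g
            kept += 1
    result = dict(out)
    result["Ka"] = ka
    result["R"] = rr
    result["gebv_sum"] = gebv_sum
    return result


def _build_block_design(basis: np.ndarray, level_idx: np.ndarray, n_levels: int) -> np.ndarray:
    """Dense records x (n_levels * k) design: row r has basis phi_r in its level's block."""
    n, k = basis.shape
    B = np.zeros((n, n_levels * k))
    cols = (level_idx[:, None] * k + np.arange(k)[None, :]).ravel()
    rows = np.repeat(np.arange(n), k)
    B[rows, cols] = basis.ravel()
    return B


def _sample_coefficient_block(rng, B, weights, resid_plus, prior_prec):
    """Draw from N(C^-1 rhs, C^-1), C = B'R^-1 B + prior_prec."""
    Bw = B * weights[:, None]
    C = Bw.T @ B + prior_prec
    rhs = Bw.T @ resid_plus
    L = np.linalg.cholesky(C)
    mean = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
    z = rng.standard_normal(rhs.size)
    return mean + np.linalg.solve(L.T, z)


def _gblup_chain_general(y, animal_idx, herd_idx, basis, class_idx, n_classes, na,
                         herd_count, Ginv, mcmc, rng, params, ka0, kp0, kh0, r0,
                         s0_k, nu_k, nu_e, s_e, grid_mean, grid_quad_mean):
    n_records = y.size
    k = basis.shape[1]
    B1 = _build_block_design(basis, animal_idx, na)
    B2 = B1.copy() if params.include_pe else None
    B3 = (
        _build_block_design(basis, herd_idx, herd_count)
        if params.include_herd
        else None
    )
    class_counts = np.bincount(class_idx, minlength=n_classes).astype(float)

    mu = float(y.mean())
    A = np.zeros((na, k))
    P = np.zeros((na, k)) if params.include_pe else None
    H = np.zeros((herd_count, k)) if params.include_herd else None
    Ka, Kp, Kh = ka0.copy(), kp0.copy(), kh0.copy()
    r_class = np.full(n_classes, float(r0))

    prior_scale = np.eye(k) * s0_k
    keep = np.zeros(mcmc.n_retained)
    out = {name: keep.copy() for name in ("mu", "Va", "Ve", "Vpe", "Vherd", "h2")}
    ka_draws = np.zeros((mcmc.n_retained, k, k))
    r_draws = np.zeros((mcmc.n_retained, n_classes))
    gebv_sum = np.zeros(na)
    kept = 0

    def contribution(Bmat, coef):
        return Bmat @ coef.ravel() if Bmat is not None else 0.0

    for it in range(mcmc.n_iter):
        weights = 1.0 / r_class[class_idx]
        fixed_part = mu
        # --- additive genetic block
        resid = (
            y - fixed_part
            - contribution(B2, P) - contribution(B3, H)
        )
        Kainv = np.linalg.inv(Ka)
        A = _sample_coefficient_block(
            rng, B1, weights, resid, np.kron(Ginv, Kainv)
        ).reshape(na, k)
        # --- permanent environment block
        if params.include_pe:
            resid = y - fixed_part - B1 @ A.ravel() - contribution(B3, H)
            Kpinv = np.linalg.inv(Kp)
            P = _sample_coefficient_block(
                rng, B2, weights, resid, np.kron(np.eye(na), Kpinv)
            ).reshape(na, k)
        # --- herd block
        if params.include_herd:
            resid = y - fixed_part - B1 @ A.ravel() - contribution(B2, P)
            Khinv = np.linalg.inv(Kh)
            H = _sample_coefficient_block(
                rng, B3, weights, resid, np.kron(np.eye(herd_count), Khinv)
            ).reshape(herd_count, k)
        # --- intercept
        resid0 = (
            y - B1 @ A.ravel() - contribution(B2, P) - contribution(B3, H)
        )
        wsum = float(weights.sum())
        mu = float(rng.normal(float(weights @ resid0) / wsum, 1.0 / np.sqrt(wsum)))
        e = resid0 - mu
        # --- (co)variance updates
        if params.update_variances:
            Ka = _sample_invwishart(rng, nu_k + na, prior_scale + A.T @ Ginv @ A)
            if params.include_pe:
                Kp = _sample_invwishart(rng, nu_k + na, prior_scale + P.T @ P)
            if params.include_herd:
                Kh = _sample_invwishart(rng, nu_k + herd_count, prior_scale + H.T @ H)
            for c in range(n_classes):
                sse = float(e[class_idx == c] @ e[class_idx == c])
                r_class[c] = _sample_scaled_inv_chi2(
                    rng, nu_e + class_counts[c], nu_e * s_e + sse
                )
        if it >= mcmc.burn_in and (it + 1 - mcmc.burn_in) % mcmc.thin == 0:
            va = float(np.sum(grid_quad_mean * Ka))
            ve = float(np.average(r_class, weights=class_counts))
            out["mu"][kept] = mu
            out["Va"][kept] = va
            out["Ve"][kept] = ve
            out["Vpe"][kept] = (
                float(np.sum(grid_quad_mean * Kp)) if params.include_pe else 0.0
            )
            out["Vherd"][kept] = (
                float(np.sum(grid_quad_mean * Kh)) if params.include_herd else 0.0
            )
            out["h2"][kept] = heritability(va, ve)
            ka_draws[kept] = Ka
            r_draws[kept] = r_class
            gebv_sum += A @ grid_mean
            kept += 1
    result = dict(out)
    result["Ka"] = ka_draws
    result["R"] = r_draws
    result["gebv_sum"] = gebv_sum
    return result


def gibbs_rr_gblup(
    adjusted: pd.DataFrame,
    G: GRMatrix,
    config: MCMCConfig | None = None,
    **params,
) -> PosteriorSummary:
    """Functional wrapper over :class:`GBLUPSampler`."""
    sampler = GBLUPSampler(mcmc=config, **params)
    sampler.fit(adjusted, G)
    return sampler.posterior_


# ---------------------------------------------------------------------------
# BayesR SNP-mixture engine
# ---------------------------------------------------------------------------

class BayesRRegressor(BaseEstimator):
    """Four-component mixture-prior whole-genome regression, by Gibbs.

    Operates on one aggregated record per genotyped animal (the intercept-
    level reduction of the trajectory model).  ``fit(W, y)`` takes the
    centered genotype matrix W (animals x SNPs) and the aggregated adjusted
    records y.  Mixture class variances are ``variance_scales`` times the
    genic variance sigma2_g; class 1 must have scale exactly 0.

    Fitted attributes: ``posterior_``, ``beta_mean_`` (posterior-mean SNP
    effects), ``pip_`` (posterior non-null inclusion probability per SNP),
    ``gebv_`` (= W beta_mean_).
    """

    def __init__(
        self,
        variance_scales: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2),
        dirichlet_concentration: float = 1.0,
        mcmc: MCMCConfig | None = None,
        prior_df: float = 4.0,
        prior_g_fraction: float = 0.5,
        prior_e_fraction: float = 0.5,
        sigma2_g: float | None = None,
        sigma2_e: float | None = None,
        update_variances: bool = True,
        update_proportions: bool = True,
        init_proportions: tuple[float, ...] | None = None,
    ):
        self.variance_scales = variance_scales
        self.dirichlet_concentration = dirichlet_concentration
        self.mcmc = mcmc
        self.prior_df = prior_df
        self.prior_g_fraction = prior_g_fraction
        self.prior_e_fraction = prior_e_fraction
        self.sigma2_g = sigma2_g
        self.sigma2_e = sigma2_e
        self.update_variances = update_variances
        self.update_proportions = update_proportions
        self.init_proportions = init_proportions

    def fit(self, W: np.ndarray, y: np.ndarray) -> "BayesRRegressor":
        scales = np.asarray(self.variance_scales, dtype=float)
        if scales.size != 4:
            logger.warning(
                "mixture with %d components instead of the standard 4", scales.size
            )
        if scales.size < 2 or scales[0] != 0.0 or (scales < 0).any():
            raise ValueError(
                "variance_scales must be non-negative with the first entry exactly 0"
            )
        W = np.asarray(W, dtype=float)
        y = np.asarray(y, dtype=float)
        n, m = W.shape
        if y.shape != (n,):
            raise ValueError("y length must equal the number of genotyped animals")
        mcmc = self.mcmc or MCMCConfig()
        vy = float(np.var(y)) or 1.0
        wtw = np.einsum("ij,ij->j", W, W)
        if (wtw == 0).any():
            raise ValueError("constant (zero-variance) SNP columns are not allowed")

        n_comp = scales.size
        pi0 = (
            np.asarray(self.init_proportions, dtype=float)
            if self.init_proportions is not None
            else np.full(n_comp, 1.0 / n_comp)
        )
        s_g = self.prior_g_fraction * vy
        s_e = self.prior_e_fraction * vy
        nu = self.prior_df

        n_ret = mcmc.n_retained
        names = ("mu", "sigma2_g", "sigma2_e", "pi_null", "n_nonnull", "h2")
        store: dict[str, list] = {nm: [] for nm in names}
        pi_draws = []
        beta_accum = np.zeros(m)
        pip_accum = np.zeros(m)
        gebv_accum = np.zeros(n)

        for rng in _chain_rngs(mcmc):
            chain = self._run_chain(
                rng, W, y, wtw, scales, pi0.copy(), mcmc,
                s_g=s_g, s_e=s_e, nu=nu, vy=vy,
            )
            for nm in names:
                store[nm].append(chain[nm])
            pi_draws.append(chain["pi"])
            beta_accum += chain["beta_sum"]
            pip_accum += chain["pip_sum"]
            gebv_accum += chain["gebv_sum"]

        denom = mcmc.n_chains * n_ret
        self.beta_mean_ = beta_accum / denom
        self.pip_ = pip_accum / denom
        self.gebv_ = gebv_accum / denom
        draws = {nm: np.asarray(v) for nm, v in store.items()}
        draws["pi"] = np.asarray(pi_draws)
        self.posterior_ = PosteriorSummary(
            engine="bayesr",
            draws=draws,
            animal_ids=[str(i) for i in range(n)],
            gebv_mean=self.gebv_,
            n_retained_per_chain=n_ret,
            config=mcmc,
            snp_summaries={"beta_mean": self.beta_mean_, "pip": self.pip_},
        )
        return self

    def _run_chain(self, rng, W, y, wtw, scales, pi, mcmc, *, s_g, s_e, nu, vy):
        n, m = W.shape
        n_comp = scales.size
        mu = float(y.mean())
        beta = np.zeros(m)
        classes = np.zeros(m, dtype=int)
        sigma2_g = self.sigma2_g if self.sigma2_g is not None else 0.1 * vy
        sigma2_e = self.sigma2_e if self.sigma2_e is not None else 0.8 * vy
        resid = y - mu  # beta starts at zero

        n_ret = mcmc.n_retained
        out = {nm: np.zeros(n_ret) for nm in
               ("mu", "sigma2_g", "sigma2_e", "pi_null", "n_nonnull", "h2")}
        pi_keep = np.zeros((n_ret, n_comp))
        beta_sum = np.zeros(m)
        pip_sum = np.zeros(m)
        gebv_sum = np.zeros(n)
        kept = 0
        order = np.arange(m)
        for it in range(mcmc.n_iter):
            rng.shuffle(order)
            for j in order:
                wj = W[:, j]
                if beta[j] != 0.0:
                    resid += wj * beta[j]
                rho = float(wj @ resid) / sigma2_e
                log_odds = np.full(n_comp, -np.inf)
                for c in range(n_comp):
                    if pi[c] <= 0.0:
                        continue
                    if scales[c] == 0.0:
                        log_odds[c] = np.log(pi[c])
                    else:
                        v = scales[c] * sigma2_g
                        cjk = wtw[j] / sigma2_e + 1.0 / v
                        log_odds[c] = (
                            np.log(pi[c]) - 0.5 * np.log(v * cjk) + 0.5 * rho * rho / cjk
                        )
                log_odds -= log_odds.max()
                probs = np.exp(log_odds)
                probs /= probs.sum()
                c = int(rng.choice(n_comp, p=probs))
                classes[j] = c
                if scales[c] == 0.0:
                    beta[j] = 0.0
                else:
                    v = scales[c] * sigma2_g
                    cjk = wtw[j] / sigma2_e + 1.0 / v
                    beta[j] = rng.normal(rho / cjk, 1.0 / np.sqrt(cjk))
                    resid -= wj * beta[j]
            # intercept
            resid += mu
            mu = float(rng.normal(resid.mean(), np.sqrt(sigma2_e / n)))
            resid -= mu
            # variances
            nonnull = scales[classes] > 0.0
            if self.update_variances:
                ss = float(np.sum(beta[nonnull] ** 2 / scales[classes[nonnull]]))
                sigma2_g = _sample_scaled_inv_chi2(
                    rng, nu + int(nonnull.sum()), nu * s_g + ss
                )
                sigma2_e = _sample_scaled_inv_chi2(
                    rng, nu + n, nu * s_e + float(resid @ resid)
                )
            if self.update_proportions:
                counts = np.bincount(classes, minlength=n_comp)
                pi = rng.dirichlet(self.dirichlet_concentration + counts)
            if it >= mcmc.burn_in and (it + 1 - mcmc.burn_in) % mcmc.thin == 0:
                gval = y - resid - mu  # = W beta
                va = float(np.var(gval))
                out["mu"][kept] = mu
                out["sigma2_g"][kept] = sigma2_g
                out["sigma2_e"][kept] = sigma2_e
                out["pi_null"][kept] = pi[0]
                out["n_nonnull"][kept] = float(nonnull.sum())
                out["h2"][kept] = heritability(va, sigma2_e)
                pi_keep[kept] = pi
                beta_sum += beta
                pip_sum += nonnull.astype(float)
                gebv_sum += gval
                kept += 1
        result = dict(out)
        result["pi"] = pi_keep
        result["beta_sum"] = beta_sum
        result["pip_sum"] = pip_sum
        result["gebv_sum"] = gebv_sum
        return result

    def predict(self, W: np.ndarray) -> np.ndarray:
        if not hasattr(self, "beta_mean_"):
            raise RuntimeError("call fit() first")
        return np.asarray(W, dtype=float) @ self.beta_mean_


def bayesr_snp_engine(
    y_bar: np.ndarray,
    W: np.ndarray,
    config: MCMCConfig | None = None,
    **params,
) -> PosteriorSummary:
    """Functional wrapper over :class:`BayesRRegressor`."""
    reg = BayesRRegressor(mcmc=config, **params)
    reg.fit(W, y_bar)
    return reg.posterior_


# ---------------------------------------------------------------------------
# GEBV reporting and convergence diagnostics
# ---------------------------------------------------------------------------

def gebv_from_posterior(summary: PosteriorSummary) -> pd.DataFrame:
    """Ranked per-animal GEBV table from either engine's posterior."""
    return summary.gebv_table()


def gebv_summary(gebv: pd.DataFrame | np.ndarray) -> dict:
    """Min / max / mean of a GEBV table or vector, as reported in summaries."""
    values = gebv["gebv"].to_numpy() if isinstance(gebv, pd.DataFrame) else np.asarray(gebv)
    if values.size == 0:
        raise ValueError("no GEBV values")
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "n": int(values.size),
    }


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is halved; R-hat compares between-half-chain and within-
    half-chain variances.  Zero within-chain variance returns 1.0 when the
    half-chains agree and inf when they do not (deliberately unmixed
    constant chains).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a (n_chains, n_draws) array")
    n = x.shape[1]
    half = n // 2
    if half < 2:
        raise ValueError("need at least 4 draws per chain")
    splits = np.vstack([x[:, :half], x[:, half : 2 * half]])
    within = splits.var(axis=1, ddof=1)
    W = float(within.mean())
    B = half * float(splits.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def convergence_diagnostics(summary: PosteriorSummary) -> pd.DataFrame:
    """Split-R-hat and effective sample size for every scalar parameter.

    With a single chain only within-chain diagnostics (ESS) are available
    and a warning is logged.
    """
    import arviz as az

    rows = []
    single = summary.config.n_chains < 2
    if single:
        logger.warning("single chain: split R-hat unavailable, reporting ESS only")
    for name in summary.scalar_names():
        x = np.asarray(summary.draws[name], dtype=float)
        if np.ptp(x) == 0:
            ess = float(x.size)  # constant chains carry no sampling noise
        else:
            ess = float(az.ess(az.convert_to_dataset(x))["x"].values)
        rows.append(
            {
                "parameter": name,
                "rhat": float("nan") if single else split_rhat(x),
                "ess": ess,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
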