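"""Genomic BLUP on pool phenotypes with the h-GRM as genetic covariance.

Model:  y = Xb + Zg + e,  var(g) = K * sigma_g^2,  var(e) = I * sigma_e^2,

where y holds the dag category of each pool (sires have no records), X
carries an intercept and sex (sires are coded male), and K is the
unit-diagonal h-GRM H over all samples.  Variance components are estimated
by restricted maximum likelihood, profiled down to a one-dimensional search
over the ratio lambda = sigma_e^2 / sigma_g^2 after an eigen-rotation of the
phenotyped block of K; genetic effects for every sample — including the
record-free sires, whose information flows entirely through their K-
covariances with the pools — come from the BLUP identity

    g_hat = sigma_g^2 * K[:, obs] V^{-1} (y_obs - X_obs b_hat).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AnalysisError, ConfigError
from .grm import POOL, SIRE, HybridGrm

log = logging.getLogger(__name__)

_LAM_BOUNDS = (1e-6, 1e6)


@dataclass
class GblupFit:
    """REML variance components and genetic solutions.

    ``gebv`` covers every sample (pools and unphenotyped sires) in dag-score
    units; ``fixed_effects`` are the GLS solutions for the X columns;
    ``boundary`` flags a variance ratio pinned at the search bounds (genetic
    variance effectively zero or residual effectively zero).
    """

    sigma_g2: float
    sigma_e2: float
    fixed_effects: pd.Series
    gebv: pd.Series
    log_reml: float
    converged: bool
    boundary: bool = False
    bending_eps: float = 0.0

    @property
    def lam(self) -> float:
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf


def _neg2_reml(log_lam, d, yt, Xt, n, r):
    """-2 * restricted log-likelihood profiled over the total variance."""
    w = d + np.exp(log_lam)
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    sign, logdet_x = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    resid = yt - Xt @ beta
    q = float(resid @ (resid / w))
    if q <= 0:
        return np.inf
    sigma_g2 = q / (n - r)
    return (n - r) * (np.log(sigma_g2) + 1.0) + float(np.sum(np.log(w))) + logdet_x


def _prepare(y, X, K, weights):
    """Validate, bend K if near-singular, and eigen-rotate the phenotyped block."""
    if not K.index.equals(X.index) or not K.index.equals(y.index):
        raise ConfigError("y, X and K must share one sample index")
    obs = y.notna().to_numpy()
    n = int(obs.sum())
    Xm = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(Xm[obs])
    if n <= r + 1:
        raise AnalysisError(f"only {n} phenotyped samples for {r} fixed effects")

    Km = K.to_numpy(dtype=float).copy()
    eig_min = float(np.linalg.eigvalsh(Km)[0])
    bending_eps = 0.0
    if eig_min < 1e-8:
        bending_eps = 1e-6 * float(np.trace(Km)) / len(Km)
        Km[np.diag_indices_from(Km)] += bending_eps
        log.warning("bending K: min eigenvalue %.3g, added %.3g to diagonal",
                    eig_min, bending_eps)

    yo = y.to_numpy(dtype=float)[obs]
    Xo = Xm[obs]
    if weights is not None:
        w_res = weights.loc[K.index].to_numpy(dtype=float)[obs]
        if (w_res <= 0).any():
            raise ConfigError("residual weights must be positive")
        rw = np.sqrt(w_res)
        yo = yo * rw
        Xo = Xo * rw[:, None]
        Koo = Km[np.ix_(obs, obs)] * np.outer(rw, rw)
    else:
        rw = None
        Koo = Km[np.ix_(obs, obs)]
    d, U = np.linalg.eigh(Koo)
    return obs, n, r, Km, rw, d, U, U.T @ yo, U.T @ Xo, bending_eps


def blup_solve(
    y: pd.Series,
    X: pd.DataFrame,
    K: pd.DataFrame,
    lam: float,
    weights: pd.Series | None = None,
) -> GblupFit:
    """Solve the mixed model at a *known* variance ratio lambda = sigma_e^2/sigma_g^2.

    The total variance is still estimated (REML-profiled) from the data;
    only the ratio is fixed.  Useful for sensitivity analysis and for
    checking the solver against a direct dense inversion.
    """
    if not lam > 0:
        raise ConfigError("lambda must be positive")
    obs, n, r, Km, rw, d, U, yt, Xt, bending_eps = _prepare(y, X, K, weights)
    w = d + lam
    Xw = Xt / w[:, None]
    xtwx = Xt.T @ Xw
    beta = np.linalg.solve(xtwx, Xw.T @ yt)
    resid_t = yt - Xt @ beta
    sigma_g2 = float(resid_t @ (resid_t / w)) / (n - r)
    # BLUP for all samples through their covariance with the phenotyped set
    vinv_resid = U @ (resid_t / w)  # = (Koo + lam I)^{-1} residuals
    K_cross = Km[:, obs] * rw[None, :] if rw is not None else Km[:, obs]
    gebv = K_cross @ vinv_resid
    sign, logdet_x = np.linalg.slogdet(xtwx)
    neg2 = (n - r) * (np.log(sigma_g2) + 1.0) + float(np.sum(np.log(w))) + logdet_x
    return GblupFit(
        sigma_g2=sigma_g2,
        sigma_e2=lam * sigma_g2,
        fixed_effects=pd.Series(beta, index=X.columns),
        gebv=pd.Series(gebv, index=K.index, name="gebv"),
        log_reml=-0.5 * neg2,
        converged=True,
        bending_eps=bending_eps,
    )


def reml_fit(
    y: pd.Series,
    X: pd.DataFrame,
    K: pd.DataFrame,
    tolerance: float = 1e-10,
    max_iter: int = 200,
    weights: pd.Series | None = None,
) -> GblupFit:
    """Fit the one-component mixed model by profile REML.

    Parameters
    ----------
    y
        Phenotypes indexed by sample id; NaN marks unphenotyped samples
        (the sires).  Only non-missing rows enter the likelihood.
    X
        Fixed-effect design for *all* samples (same index as K).
    K
        Symmetric genetic covariance structure with unit-scale diagonal;
        bent by ``eps * I`` (eps = 1e-6 * trace/n) if its minimum eigenvalue
        falls below 1e-8, which near-singular pooled-data matrices can do.
    weights
        Optional residual weights: var(e_i) = sigma_e^2 / weights_i (e.g.
        pool member counts).  Default: homoscedastic residuals.
    max_iter / tolerance
        Passed to the bounded scalar search over log(lambda).

    Non-convergence returns a fit with ``converged=False`` and a warning
    rather than raising; a ratio at the search boundary is flagged.
    """
    obs, n, r, Km, rw, d, U, yt, Xt, bending_eps = _prepare(y, X, K, weights)

    res = optimize.minimize_scalar(
        _neg2_reml,
        bounds=np.log(_LAM_BOUNDS),
        args=(d, yt, Xt, n, r),
        method="bounded",
        options={"xatol": tolerance, "maxiter": max_iter},
    )
    converged = bool(res.success) and bool(np.isfinite(res.fun))
    if not np.isfinite(res.fun):
        # bounded search failed outright: fall back to a coarse grid
        grid = np.linspace(*np.log(_LAM_BOUNDS), 121)
        vals = [_neg2_reml(g, d, yt, Xt, n, r) for g in grid]
        best = int(np.argmin(vals))
        res.x, res.fun = grid[best], vals[best]
        converged = bool(np.isfinite(res.fun))
        log.warning("REML line search failed; using coarse-grid ratio")
    lam = float(np.exp(res.x))
    boundary = (
        lam <= _LAM_BOUNDS[0] * (1 + 1e-3) or lam >= _LAM_BOUNDS[1] * (1 - 1e-3)
    )
    if not converged:
        log.warning("REML did not converge in %d iterations", max_iter)

    fit = blup_solve(y, X, K, lam, weights=weights)
    fit.converged = converged
    fit.boundary = boundary
    return fit


def fit_gblup(
    grm: HybridGrm,
    meta: pd.DataFrame,
    use_h: bool = True,
    weight_by_members: bool = False,
) -> GblupFit:
    """gBLUP on the pipeline's h-GRM: pool dag scores as records, sires missing.

    Sex is the single fixed effect besides the intercept; sires (all male)
    take the male code.  ``weight_by_members`` divides the residual variance
    of each pool record by its nominal member count.
    """
    K = grm.h if use_h else grm.gstar
    ids = K.index
    roles = grm.roles.loc[ids]
    y = pd.Series(np.nan, index=ids, name="dag_score")
    pool_ids = ids[roles == POOL]
    y.loc[pool_ids] = meta.loc[pool_ids, "dag_score"].astype(float)
    sex = pd.Series("male", index=ids)
    sex.loc[pool_ids] = meta.loc[pool_ids, "sex"]
    X = pd.DataFrame(
        {"intercept": 1.0, "sex_male": (sex == "male").astype(float)}, index=ids
    )
    weights = None
    if weight_by_members:
        weights = pd.Series(1.0, index=ids)
        weights.loc[pool_ids] = meta.loc[pool_ids, "n_members"].astype(float)
    return reml_fit(y, X, K, weights=weights)


def slope_gebv_concordance(slopes: pd.Series, gebvs: pd.Series) -> dict:
    """Pearson and Spearman agreement between regression slopes and GEBVs.

    Both quantities increase with a sire's genetic propensity for high dag
    scores, so strong positive correlations mean the cheap regression
    ranking and the gBLUP ranking tell the same story.
    """
    shared = slopes.index.intersection(gebvs.index)
    if len(shared) < 3:
        raise AnalysisError("need at least 3 sires for a concordance estimate")
    a = slopes.loc[shared].to_numpy(dtype=float)
    b = gebvs.loc[shared].to_numpy(dtype=float)
    return {
        "pearson": float(stats.pearsonr(a, b).statistic),
        "spearman": float(stats.spearmanr(a, b).statistic),
        "n_sires": int(len(shared)),
    }
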