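"""Per-sire regression of pool relationships on pool phenotype.

For sire i with relationship Y_ij to pool j, fit by ordinary least squares

    Y_ij = b0 + b1 * sex_j + b2 * score_j + e_ij

where sex is coded 0 (female) / 1 (male) and the dag score enters as a
single numeric covariate 1-5.  A positive slope b2 means the sire is more
related to high-score (heavily soiled) pools — genetically unfavourable; a
negative slope marks a favourable sire.  Slope p-values come from the
two-sided t test with n_pools - 3 degrees of freedom.

Significance is calibrated globally, not per sire: pool scores are permuted
within sex, all sire regressions are refit per permutation, and the counts
of sires per significance class (observed vs permuted) are compared with a
Pearson chi-square statistic whose p-value is obtained by Monte-Carlo
multinomial resampling rather than the asymptotic distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigError
from .grm import POOL, SIRE, HybridGrm

log = logging.getLogger(__name__)

#: Descending significance levels tabulated for the calibration summary.
DEFAULT_LEVELS: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001, 0.0005)

_TINY = np.finfo(float).tiny


@dataclass
class PermutationSummary:
    """Observed vs permuted significance-class proportions.

    Proportions are cumulative: the fraction of (sire x fit) slope p-values
    at or below each level.  ``permuted_p`` has shape (n_perm, n_sires).
    """

    levels: tuple[float, ...]
    observed_proportions: np.ndarray
    permuted_proportions: np.ndarray
    n_perm: int
    n_sires: int
    observed_p: np.ndarray
    permuted_p: np.ndarray
    chisq_p: float | None = None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.observed_proportions, self.permuted_proportions],
            index=["observed", "permuted"],
            columns=[str(l) for l in self.levels],
        )


def _design(meta: pd.DataFrame, scores: np.ndarray | None = None) -> np.ndarray:
    sex = (meta["sex"].to_numpy() == "male").astype(float)
    sc = meta["dag_score"].to_numpy(dtype=float) if scores is None else scores
    X = np.column_stack([np.ones(len(meta)), sex, sc])
    if np.linalg.matrix_rank(X) < 3:
        raise AnalysisError(
            "rank-deficient design: pools must vary in dag score (and the "
            "sex column must not duplicate it)"
        )
    return X


def _ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each column of Y on X; returns (coef 3 x k, slope p-values k).

    A residual-free fit is p = 1 when the slope is exactly zero (no
    variation) and machine-tiny otherwise (perfect linear signal).
    """
    n = X.shape[0]
    if n < 4:
        raise AnalysisError(f"need at least 4 pools, got {n}")
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coef
    dof = n - X.shape[1]
    s2 = np.einsum("ij,ij->j", resid, resid) / dof
    var_b2 = s2 * xtx_inv[2, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef[2] / np.sqrt(var_b2)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    degenerate = var_b2 <= 0
    if np.any(degenerate):
        p = np.where(degenerate & (np.abs(coef[2]) > 0), _TINY, p)
        p = np.where(degenerate & (np.abs(coef[2]) == 0), 1.0, p)
    constant = np.ptp(Y, axis=0) == 0
    if np.any(constant):  # no variation at all: slope exactly 0, p exactly 1
        coef[:, constant] = 0.0
        coef[0, constant] = Y[0, constant]
        p[constant] = 1.0
    return coef, np.clip(p, _TINY, 1.0)


def _pool_relationships(grm: HybridGrm, use_h: bool = True) -> pd.DataFrame:
    """Pools x sires matrix of relationship values (H by default)."""
    m = grm.h if use_h else grm.gstar
    sire_ids = grm.roles.index[grm.roles == SIRE]
    pool_ids = grm.roles.index[grm.roles == POOL]
    if len(pool_ids) < 4:
        raise AnalysisError("need at least 4 pools for the sire regression")
    return m.loc[pool_ids, sire_ids]


def fit_sire_slopes(
    grm: HybridGrm, meta: pd.DataFrame, use_h: bool = True
) -> pd.DataFrame:
    """Fit the pool-relationship regression for every genotyped sire.

    Returns a frame indexed by sire id with columns beta0, beta1 (sex),
    beta2 (dag-score slope), p_value (two-sided t on beta2), n_pools.
    """
    Y = _pool_relationships(grm, use_h)
    X = _design(meta.loc[Y.index])
    coef, p = _ols_multi(X, Y.to_numpy())
    return pd.DataFrame(
        {
            "beta0": coef[0],
            "beta1": coef[1],
            "beta2": coef[2],
            "p_value": p,
            "n_pools": len(Y),
        },
        index=Y.columns.rename("sire_id"),
    )


def sire_slope(grm: HybridGrm, meta: pd.DataFrame, sire_id: str) -> pd.Series:
    """Single-sire convenience wrapper around :func:`fit_sire_slopes`."""
    table = fit_sire_slopes(grm, meta)
    if sire_id not in table.index:
        raise AnalysisError(f"unknown sire {sire_id!r}")
    return table.loc[sire_id]


def permute_null(
    grm: HybridGrm,
    meta: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    use_h: bool = True,
) -> PermutationSummary:
    """Build the permutation null by shuffling dag scores within sex.

    Sex labels stay fixed; each permutation refits every sire and the
    permuted proportions pool all sire x permutation p-values.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    levels = tuple(sorted(levels, reverse=True))
    Y = _pool_relationships(grm, use_h)
    meta = meta.loc[Y.index]
    for sex, grp in meta.groupby("sex"):
        if grp["dag_score"].nunique() < 2:
            raise AnalysisError(f"pools of sex {sex!r} carry a single dag score")
    Ynp = Y.to_numpy()
    _, observed_p = _ols_multi(_design(meta), Ynp)

    rng = np.random.default_rng(seed)
    scores = meta["dag_score"].to_numpy(dtype=float)
    sex_groups = [np.flatnonzero(meta["sex"].to_numpy() == s) for s in
                  pd.unique(meta["sex"])]
    permuted = np.empty((n_perm, Ynp.shape[1]))
    for k in range(n_perm):
        shuffled = scores.copy()
        for idx in sex_groups:
            shuffled[idx] = shuffled[rng.permutation(idx)]
        _, permuted[k] = _ols_multi(_design(meta, shuffled), Ynp)

    obs_prop = np.array([(observed_p <= l).mean() for l in levels])
    perm_prop = np.array([(permuted <= l).mean() for l in levels])
    return PermutationSummary(
        levels=levels,
        observed_proportions=obs_prop,
        permuted_proportions=perm_prop,
        n_perm=n_perm,
        n_sires=Ynp.shape[1],
        observed_p=observed_p,
        permuted_p=permuted,
    )


def _class_bins(p_values: np.ndarray, levels_desc: tuple[float, ...]) -> np.ndarray:
    """Counts per disjoint significance class, tightest first.

    Classes: p <= levels[-1]; (levels[k+1], levels[k]] for consecutive
    levels; and p > levels[0] ("not significant").
    """
    edges = np.array([0.0, *sorted(levels_desc), 1.0])
    counts, _ = np.histogram(p_values, bins=edges)
    return counts  # tightest class first


def calibration_test(
    observed_p: np.ndarray,
    permuted_p: np.ndarray,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Simulated Pearson chi-square comparing significance-class counts.

    Sires are binned into disjoint classes by observed p-value; expected
    class probabilities come from the pooled permuted p-values.  The Pearson
    statistic's p-value is estimated by drawing ``n_sim`` multinomial
    samples under the expected probabilities (not the asymptotic chi-square
    law).  Classes with zero expected probability are merged with their
    next-less-significant neighbour.
    """
    levels = tuple(sorted(levels, reverse=True))
    observed_p = np.asarray(observed_p, dtype=float)
    permuted_p = np.asarray(permuted_p, dtype=float).ravel()
    obs = _class_bins(observed_p, levels).astype(float)
    exp_counts = _class_bins(permuted_p, levels).astype(float)
    probs = exp_counts / exp_counts.sum()

    while len(probs) > 1 and (probs == 0).any():
        k = int(np.flatnonzero(probs == 0)[0])
        j = k + 1 if k + 1 < len(probs) else k - 1
        if obs[k] > 0:
            log.warning(
                "significance class %d has zero expected probability but %d "
                "observed sires; merging with neighbour", k, int(obs[k])
            )
        obs[j] += obs[k]
        probs[j] += probs[k]
        obs = np.delete(obs, k)
        probs = np.delete(probs, k)

    n = int(obs.sum())
    expected = n * probs
    stat_obs = float(np.sum((obs - expected) ** 2 / expected))
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, probs, size=n_sim)
    stat_sim = np.sum((sims - expected) ** 2 / expected, axis=1)
    return float((1 + np.sum(stat_sim >= stat_obs - 1e-12)) / (n_sim + 1))


def summarize_significance(
    grm: HybridGrm,
    meta: pd.DataFrame,
    n_perm: int = 100,
    n_sim: int = 2000,
    seed: int = 0,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    use_h: bool = True,
) -> PermutationSummary:
    """Run the permutation null and attach the simulated chi-square p-value."""
    summary = permute_null(grm, meta, n_perm=n_perm, seed=seed, levels=levels, use_h=use_h)
    summary.chisq_p = calibration_test(
        summary.observed_p, summary.permuted_p, levels=summary.levels,
        n_sim=n_sim, seed=seed + 1,
    )
    return summary
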