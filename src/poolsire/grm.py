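"""Hybrid genomic relationship matrix (h-GRM) from sire + pool allele frequencies.

The h-GRM extends VanRaden's first GRM to a mixture of individually
genotyped samples (sires, BAF in {0, 0.5, 1}) and DNA pools (BAF in [0, 1]):

    M* = (Bfreq - 0.5) * 2                 entries in [-1, 1]
    Z* = M* - P*,   P*_l = (p_l - 0.5) * 2 per-locus centring
    G* = Z* Z*' / (2 * sum_l p_l (1 - p_l))

with p_l the cross-sample mean B-allele frequency at locus l (missing calls
counted as 0.5).  Because the effective number of contributors to a pool is
unknown (DNA concentrations vary), G* is rescaled to unit diagonal,

    H_ij = G*_ij / sqrt(G*_ii * G*_jj),

which absorbs pool-size effects analytically.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigError
from .flock import PoolBafMatrix, SireGenotypes

log = logging.getLogger(__name__)

SIRE = "sire"
POOL = "pool"


@dataclass
class HybridGrm:
    """G* and its unit-diagonal scaling H over sires and pools.

    ``roles`` maps each sample id to "sire" or "pool"; ``pair_counts``
    records, per pair, the loci with non-missing data in both samples (the
    GCTA triangle's N column); ``denominator`` is 2*sum p(1-p).
    """

    gstar: pd.DataFrame
    h: pd.DataFrame
    roles: pd.Series
    denominator: float
    n_loci: int
    pair_counts: np.ndarray | None = None

    @property
    def sample_ids(self) -> pd.Index:
        return self.gstar.index

    def block(self, matrix: str, rows: str, cols: str) -> pd.DataFrame:
        """Extract a role block, e.g. ``block("h", "sire", "pool")``."""
        m = self.h if matrix == "h" else self.gstar
        return m.loc[self.roles == rows, self.roles == cols]


def stack_baf(sires: SireGenotypes, pools: PoolBafMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Stack genotyped-sire and pool BAF rows over a shared locus panel."""
    if not sires.loci.equals(pools.loci):
        raise AnalysisError("sire and pool locus panels differ; align them first")
    stacked = pd.concat([sires.genotyped_calls, pools.baf])
    if stacked.index.duplicated().any():
        dup = stacked.index[stacked.index.duplicated()][0]
        raise ConfigError(f"duplicate sample id across sires and pools: {dup!r}")
    roles = pd.Series(
        [SIRE] * len(sires.genotyped) + [POOL] * len(pools.baf), index=stacked.index
    )
    return stacked, roles


def encode_mstar(baf: pd.DataFrame) -> pd.DataFrame:
    """Map B-allele frequencies [0, 1] to M* in [-1, 1]; NaN preserved."""
    values = baf.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ConfigError(
            f"BAF out of [0, 1] at sample {baf.index[i]!r}, locus {baf.columns[j]!r}: "
            f"{values[i, j]}"
        )
    return pd.DataFrame((values - 0.5) * 2.0, index=baf.index, columns=baf.columns)


def allele_freqs(baf: pd.DataFrame, weights: np.ndarray | None = None) -> np.ndarray:
    """Per-locus mean B-allele frequency with missing entries counted as 0.5.

    By default every sample row counts equally (a 40-animal pool the same as
    one sire); pass ``weights`` to weight rows, e.g. by pool member count.
    """
    values = baf.to_numpy(dtype=float)
    filled = np.where(np.isnan(values), 0.5, values)
    if weights is None:
        return filled.mean(axis=0)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(baf),) or w.sum() <= 0:
        raise ConfigError("weights must be one positive value per sample row")
    return (w / w.sum()) @ filled


def gstar(
    baf: pd.DataFrame,
    p: np.ndarray,
    roles: pd.Series | None = None,
) -> HybridGrm:
    """Compute G* = Z*Z*' / (2 sum p(1-p)) with missing entries centred out.

    A missing M* entry is set to its P* value so it contributes zero to Z*;
    fixed loci (p in {0, 1}) contribute zero to both numerator and
    denominator and are retained (rare alleles are informative here, so no
    MAF filter applies).
    """
    mstar = encode_mstar(baf).to_numpy()
    pstar = (np.asarray(p, dtype=float) - 0.5) * 2.0
    z = mstar - pstar
    missing = np.isnan(z)
    z[missing] = 0.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise AnalysisError("zero denominator: every locus is fixed (p in {0, 1})")
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against float round-off
    nonmiss = (~missing).astype(np.int64)
    if roles is None:
        roles = pd.Series(SIRE, index=baf.index)
    gdf = pd.DataFrame(g, index=baf.index, columns=baf.index)
    return HybridGrm(
        gstar=gdf,
        h=None,  # filled by scale_h
        roles=roles,
        denominator=denom,
        n_loci=baf.shape[1],
        pair_counts=nonmiss @ nonmiss.T,
    )


def scale_h(grm: HybridGrm) -> HybridGrm:
    """Scale G* to unit diagonal: H_ij = G*_ij / sqrt(G*_ii G*_jj)."""
    g = grm.gstar.to_numpy()
    d = np.diag(g)
    if (d <= 0).any():
        bad = grm.gstar.index[int(np.argmax(d <= 0))]
        raise AnalysisError(
            f"nonpositive G* diagonal for sample {bad!r}; the sample is "
            "degenerate (constant at the reference frequencies)"
        )
    s = np.sqrt(d)
    h = g / np.outer(s, s)
    np.fill_diagonal(h, 1.0)
    grm.h = pd.DataFrame(h, index=grm.gstar.index, columns=grm.gstar.columns)
    return grm


def build_hgrm(
    sires: SireGenotypes,
    pools: PoolBafMatrix,
    freq_source: str = "all",
    weight_freq_by_members: bool = False,
) -> HybridGrm:
    """Build the full h-GRM (G* and H) from aligned sire and pool tables.

    ``freq_source`` selects which rows define the reference frequencies p:
    "all" (default), "sires" or "pools".  ``weight_freq_by_members`` weights
    pool rows by their nominal member count when computing p.
    """
    stacked, roles = stack_baf(sires, pools)
    if freq_source == "all":
        sub = stacked
    elif freq_source == "sires":
        sub = stacked.loc[roles == SIRE]
    elif freq_source == "pools":
        sub = stacked.loc[roles == POOL]
    else:
        raise ConfigError(f"freq_source must be all|sires|pools, got {freq_source!r}")
    weights = None
    if weight_freq_by_members:
        counts = pools.meta["n_members"]
        weights = np.array(
            [counts.get(i, 1.0) if roles.loc[i] == POOL else 1.0 for i in sub.index],
            dtype=float,
        )
    p = allele_freqs(sub, weights=weights)
    return scale_h(gstar(stacked, p, roles))


def check_psd(matrix: pd.DataFrame, rel_tol: float = 1e-8) -> float:
    """Assert positive semidefiniteness; returns the minimum eigenvalue.

    Tolerance is relative to the trace: min eigenvalue >= -rel_tol * trace.
    """
    m = matrix.to_numpy()
    if not np.allclose(m, m.T, atol=1e-8 * max(1.0, np.abs(m).max())):
        raise AnalysisError("matrix is not symmetric")
    eigmin = float(np.linalg.eigvalsh(m)[0])
    if eigmin < -rel_tol * float(np.trace(m)):
        raise AnalysisError(f"matrix is not PSD: min eigenvalue {eigmin:g}")
    return eigmin
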