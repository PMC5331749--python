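"""Tabular genotype/pool I/O and GCTA-style GRM text export.

Internal canon is B-allele-frequency coding: sire tables hold {0, 0.5, 1, NA}
(0/1/2 dosage accepted on read and halved), pool tables hold reals in [0, 1].
Relationship matrices are exchanged in the GCTA text convention: a ``.grm.id``
file (family id = sample role, individual id) and a lower-triangle file with
rows ``i  j  n_loci  value`` (1-based, i >= j).
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .flock import PoolBafMatrix, SireGenotypes

log = logging.getLogger(__name__)

SIRE_VALUES = (0.0, 0.5, 1.0)
DOSAGE_VALUES = (0.0, 1.0, 2.0)


def _read_table(path, na_values) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    loci = header[1:]
    seen = pd.Index(loci)
    if seen.duplicated().any():
        raise ParseError(f"{path}: duplicated locus id {seen[seen.duplicated()][0]!r}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(na_values), keep_default_na=False
    )
    df.columns = seen  # undo pandas' renaming of duplicate headers
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicated sample id {df.index[df.index.duplicated()][0]!r}")
    return df.astype(float)


def _first_offender(df: pd.DataFrame, bad: np.ndarray) -> str:
    i, j = np.argwhere(bad)[0]
    return f"row {df.index[i]!r}, column {df.columns[j]!r} = {df.to_numpy()[i, j]}"


def read_sire_table(
    path, dosage: bool = False, na_values: tuple[str, ...] = ("NA", "")
) -> SireGenotypes:
    """Read a sires x loci TSV of {0, 0.5, 1} calls (or 0/1/2 with dosage=True)."""
    df = _read_table(path, na_values)
    allowed = DOSAGE_VALUES if dosage else SIRE_VALUES
    values = df.to_numpy()
    ok = np.isnan(values)
    for v in allowed:
        ok |= np.isclose(values, v, atol=1e-9)
    if not ok.all():
        raise ParseError(
            f"{path}: sire genotype outside {set(allowed)} at {_first_offender(df, ~ok)}"
        )
    if dosage:
        df = df / 2.0
    return SireGenotypes(calls=df)


def read_pool_table(
    path, meta_path=None, na_values: tuple[str, ...] = ("NA", "")
) -> PoolBafMatrix:
    """Read a pools x loci TSV of allele frequencies in [0, 1], plus metadata CSV.

    The metadata CSV needs columns pool_id, sex, dag_score, n_members; without
    it an empty metadata frame is attached (enough for GRM building, not for
    regression or gBLUP).
    """
    df = _read_table(path, na_values)
    values = df.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (values < 0) | (values > 1)
    if bad.any():
        raise ParseError(f"{path}: pool BAF outside [0, 1] at {_first_offender(df, bad)}")
    if meta_path is None:
        meta = pd.DataFrame(
            index=df.index, columns=["sex", "dag_score", "n_members"]
        )
    else:
        meta = pd.read_csv(meta_path).set_index("pool_id")
        missing = df.index.difference(meta.index)
        if len(missing):
            raise ParseError(f"{meta_path}: no metadata for pool {missing[0]!r}")
        meta = meta.loc[df.index]
    return PoolBafMatrix(baf=df, meta=meta)


def read_genotype_table(path, role: str, **kwargs):
    """Dispatch on sample role: "sire" -> SireGenotypes, "pool" -> PoolBafMatrix."""
    if role == "sire":
        return read_sire_table(path, **kwargs)
    if role == "pool":
        return read_pool_table(path, **kwargs)
    raise ParseError(f"role must be 'sire' or 'pool', got {role!r}")


def write_sire_table(sires: SireGenotypes, path) -> None:
    sires.calls.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")


def write_pool_table(pools: PoolBafMatrix, path, meta_path=None) -> None:
    pools.baf.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    if meta_path is not None:
        pools.meta.to_csv(meta_path)


def align_loci(
    sires: SireGenotypes, pools: PoolBafMatrix
) -> tuple[SireGenotypes, PoolBafMatrix]:
    """Restrict both tables to their shared loci, preserving sire panel order."""
    shared = sires.loci.intersection(pools.loci, sort=False)
    if len(shared) == 0:
        raise ParseError("sire and pool locus panels are disjoint")
    dropped = (len(sires.loci) - len(shared)) + (len(pools.loci) - len(shared))
    if dropped:
        log.warning("align_loci: dropped %d unshared locus columns", dropped)
    return (
        SireGenotypes(
            calls=sires.calls.loc[:, shared],
            genotyped=sires.genotyped,
            founder_freqs=None,
        ),
        PoolBafMatrix(baf=pools.baf.loc[:, shared], meta=pools.meta),
    )


def write_grm(
    matrix: pd.DataFrame,
    roles: pd.Series,
    prefix,
    pair_counts=None,
    use_gzip: bool = False,
) -> None:
    """Write a symmetric relationship matrix in GCTA text format.

    ``prefix`` produces ``prefix.grm.id`` and ``prefix.grm`` (``.grm.gz`` if
    gzip requested).  ``pair_counts`` is the per-pair non-missing locus count
    (scalar or matrix); it defaults to 0 when unknown.
    """
    m = matrix.to_numpy()
    if not np.allclose(m, m.T, atol=1e-8):
        raise ParseError("refusing to write an asymmetric relationship matrix")
    prefix = str(prefix)
    ids = matrix.index
    with open(prefix + ".grm.id", "w") as fh:
        for sid in ids:
            fh.write(f"{roles.loc[sid]}\t{sid}\n")
    counts = pair_counts if pair_counts is not None else 0
    counts = np.broadcast_to(np.asarray(counts), m.shape)
    opener = gzip.open if use_gzip else open
    suffix = ".grm.gz" if use_gzip else ".grm"
    with opener(prefix + suffix, "wt") as fh:
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{int(counts[i, j])}\t{m[i, j]:.17g}\n")


def read_grm(prefix) -> tuple[pd.DataFrame, pd.Series]:
    """Read a GCTA text GRM written by :func:`write_grm` back into a matrix."""
    prefix = str(prefix)
    idpath = Path(prefix + ".grm.id")
    if not idpath.exists():
        raise ParseError(f"no such file: {idpath}")
    iddf = pd.read_csv(idpath, sep="\t", header=None, names=["role", "id"])
    tripath = Path(prefix + ".grm")
    if not tripath.exists():
        tripath = Path(prefix + ".grm.gz")
    tri = pd.read_csv(tripath, sep="\t", header=None, names=["i", "j", "n", "value"])
    n = len(iddf)
    m = np.zeros((n, n))
    m[tri["i"] - 1, tri["j"] - 1] = tri["value"]
    m = m + np.tril(m, -1).T
    ids = pd.Index(iddf["id"])
    return (
        pd.DataFrame(m, index=ids, columns=ids),
        pd.Series(iddf["role"].to_numpy(), index=ids),
    )
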