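"""Synthetic group-mated flock with phenotype-stratified DNA pools.

Generates the statistical structure the downstream analysis assumes: sires
genotyped individually, a large progeny drop of unknown pedigree carrying a
1-5 categorical score from a liability-threshold model, pools formed within
sex x score cells, and pooled B-allele frequencies perturbed by unequal
per-animal DNA contributions.

All genotypes are coded as B-allele frequencies: {0, 0.5, 1} for an
individual diploid, a real in [0, 1] for a pool.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FlockConfig
from .errors import ConfigError

log = logging.getLogger(__name__)

SEXES = ("male", "female")


@dataclass
class SireGenotypes:
    """Sires x loci B-allele-frequency genotype calls.

    ``calls`` holds values in {0, 0.5, 1} with NaN for missing; ``genotyped``
    flags the sires whose DNA is actually available to the analysis (simulated
    flocks carry genotypes for every sire so progeny can be gene-dropped, but
    only the flagged subset enters the relationship matrix).  ``founder_freqs``
    are the per-locus allele frequencies the sires were drawn from; they are
    simulation truth, never visible to the estimator.
    """

    calls: pd.DataFrame
    genotyped: pd.Index | None = None
    founder_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.genotyped is None:
            self.genotyped = self.calls.index

    @property
    def loci(self) -> pd.Index:
        return self.calls.columns

    @property
    def genotyped_calls(self) -> pd.DataFrame:
        return self.calls.loc[self.genotyped]


@dataclass
class PoolBafMatrix:
    """Pools x loci allele frequencies plus pool metadata.

    ``meta`` is indexed by pool id with columns ``sex`` (male/female),
    ``dag_score`` (1-5) and ``n_members`` (nominal pool size).
    """

    baf: pd.DataFrame
    meta: pd.DataFrame

    @property
    def loci(self) -> pd.Index:
        return self.baf.columns


@dataclass
class ProgenyTable:
    """One row per progeny plus the aligned genotype matrix.

    ``table`` columns: animal_id (index), sire_id, sex, true_bv (the animal's
    own additive genetic value on the liability scale), liability, dag_score.
    ``genotypes`` is n_progeny x n_loci float32 BAF, row order matching
    ``table``.
    """

    table: pd.DataFrame
    genotypes: np.ndarray
    loci: pd.Index


@dataclass(frozen=True)
class PoolAssignment:
    pool_id: str
    sex: str
    dag_score: int
    members: tuple[str, ...]

    @property
    def nominal_size(self) -> int:
        return len(self.members)


@dataclass
class Flock:
    """A complete simulated dataset: everything the pipeline consumes plus truth."""

    config: FlockConfig
    sires: SireGenotypes
    progeny: ProgenyTable
    assignments: list[PoolAssignment]
    pools: PoolBafMatrix
    sire_truth: pd.Series  # true breeding value per sire, liability units


def simulate_sires(config: FlockConfig, rng: np.random.Generator) -> SireGenotypes:
    """Draw sire genotypes under Hardy-Weinberg equilibrium.

    Per-locus allele frequencies are uniform on [maf_low, maf_high]; each
    sire's genotype at a locus is Binomial(2, q)/2, coded 0/0.5/1.  Only the
    first ``n_genotyped_sires`` sires are flagged as genotyped.
    """
    q = rng.uniform(config.maf_low, config.maf_high, size=config.n_loci)
    calls = rng.binomial(2, q, size=(config.n_sires, config.n_loci)) / 2.0
    ids = pd.Index([f"S{i + 1:02d}" for i in range(config.n_sires)], name="sire_id")
    loci = pd.Index([f"L{j + 1:05d}" for j in range(config.n_loci)], name="locus")
    return SireGenotypes(
        calls=pd.DataFrame(calls, index=ids, columns=loci),
        genotyped=ids[: config.n_genotyped_sires],
        founder_freqs=q,
    )


def simulate_progeny(
    sires: SireGenotypes, config: FlockConfig, rng: np.random.Generator
) -> tuple[ProgenyTable, pd.Series]:
    """Gene-drop a progeny generation and score it on the liability scale.

    Each progeny gets a sire uniformly at random (group mating; the pedigree
    is recorded only as simulation truth).  The paternal allele is sampled
    from the sire's genotype, the maternal allele from the founder allele
    frequency (dams are not modelled individually).  Liability is the
    animal's additive genetic value plus a normal environmental deviate; the
    per-locus effects are drawn once and rescaled so the genetic share of
    liability variance equals the configured heritability.  The dag score is
    1 plus the number of thresholds below the liability.

    Returns the progeny table and the true breeding value of every sire.
    """
    if sires.founder_freqs is None:
        raise ConfigError("simulate_progeny requires sires with founder_freqs")
    h2 = config.heritability
    q = sires.founder_freqs
    n, L = config.n_progeny, config.n_loci

    raw = rng.normal(size=L)
    va = float(np.sum(raw**2 * 2.0 * q * (1.0 - q)))
    scale = np.sqrt(h2 / va) if h2 > 0 and va > 0 else 0.0
    effects = raw * scale

    sire_calls = sires.calls.to_numpy()
    sire_idx = rng.integers(0, config.n_sires, size=n)
    paternal = (rng.random((n, L)) < sire_calls[sire_idx]).astype(np.float32)
    maternal = (rng.random((n, L)) < q).astype(np.float32)
    baf = (paternal + maternal) / np.float32(2.0)

    # additive genetic value, centred at the founder mean dosage 2q
    gv = 2.0 * (baf @ effects) - 2.0 * float(q @ effects)
    sex = np.where(rng.integers(0, 2, size=n) == 1, "male", "female")
    env = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)
    liability = gv + env + np.where(sex == "male", config.sex_effect, 0.0)
    thresholds = np.asarray(config.category_thresholds)
    dag = 1 + np.searchsorted(thresholds, liability, side="left")

    ids = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="animal_id")
    table = pd.DataFrame(
        {
            "sire_id": sires.calls.index.to_numpy()[sire_idx],
            "sex": sex,
            "true_bv": gv,
            "liability": liability,
            "dag_score": dag.astype(int),
        },
        index=ids,
    )
    sire_bv = pd.Series(
        2.0 * (sire_calls @ effects) - 2.0 * float(q @ effects),
        index=sires.calls.index,
        name="true_bv",
    )
    return ProgenyTable(table=table, genotypes=baf, loci=sires.loci), sire_bv


def assign_pools(
    progeny: ProgenyTable, config: FlockConfig, rng: np.random.Generator
) -> list[PoolAssignment]:
    """Form replicate pools within each sex x dag-score cell.

    At most ``max_per_cell`` animals are retained per cell — by default the
    first through the race, emulating sampling until the cap is reached —
    then the retained animals are shuffled and split into ``n_replicates``
    pools whose sizes differ by at most one.  Empty cells are skipped with a
    warning.
    """
    table = progeny.table
    pools: list[PoolAssignment] = []
    for sex in SEXES:
        for score in range(1, 6):
            cell = table.index[(table["sex"] == sex) & (table["dag_score"] == score)]
            if len(cell) == 0:
                log.warning("no animals in cell sex=%s dag_score=%d; omitted", sex, score)
                continue
            if config.retention == "first_come":
                retained = cell[: config.max_per_cell]
            else:
                keep = min(config.max_per_cell, len(cell))
                retained = pd.Index(rng.choice(cell, size=keep, replace=False))
            shuffled = retained.to_numpy()[rng.permutation(len(retained))]
            for rep, chunk in enumerate(np.array_split(shuffled, config.n_replicates)):
                if len(chunk) == 0:
                    log.warning(
                        "cell sex=%s dag_score=%d too small for %d replicates",
                        sex, score, config.n_replicates,
                    )
                    continue
                pools.append(
                    PoolAssignment(
                        pool_id=f"{'M' if sex == 'male' else 'F'}{score}r{rep + 1}",
                        sex=sex,
                        dag_score=score,
                        members=tuple(chunk),
                    )
                )
    return pools


def pool_baf(
    progeny: ProgenyTable,
    assignments: list[PoolAssignment],
    contribution_concentration: float,
    rng: np.random.Generator,
) -> PoolBafMatrix:
    """Pool member genotypes into per-pool allele frequencies.

    Member contribution weights are symmetric-Dirichlet with the given
    concentration (``inf`` gives exactly equal weights), modelling unequal
    DNA concentration across blood samples; the pool BAF at each locus is
    the weighted mean of member B-allele frequencies.
    """
    if not contribution_concentration > 0:
        raise ConfigError("contribution_concentration must be positive")
    row_pos = pd.Series(np.arange(len(progeny.table)), index=progeny.table.index)
    rows, meta = [], []
    for pool in assignments:
        missing = [m for m in pool.members if m not in row_pos.index]
        if missing:
            raise ConfigError(f"pool {pool.pool_id}: unknown members {missing[:5]}")
        idx = row_pos[list(pool.members)].to_numpy()
        k = len(idx)
        if k == 1 or np.isinf(contribution_concentration):
            w = np.full(k, 1.0 / k)
        else:
            w = rng.dirichlet(np.full(k, contribution_concentration))
        rows.append(w @ progeny.genotypes[idx].astype(np.float64))
        meta.append((pool.pool_id, pool.sex, pool.dag_score, k))
    meta_df = pd.DataFrame(
        meta, columns=["pool_id", "sex", "dag_score", "n_members"]
    ).set_index("pool_id")
    baf = pd.DataFrame(rows, index=meta_df.index, columns=progeny.loci)
    return PoolBafMatrix(baf=baf, meta=meta_df)


def simulate_flock(config: FlockConfig) -> Flock:
    """Run the full generator under the config's single seed."""
    rng = np.random.default_rng(config.seed)
    sires = simulate_sires(config, rng)
    progeny, sire_bv = simulate_progeny(sires, config, rng)
    assignments = assign_pools(progeny, config, rng)
    pools = pool_baf(progeny, assignments, config.contribution_concentration, rng)
    return Flock(
        config=config,
        sires=sires,
        progeny=progeny,
        assignments=assignments,
        pools=pools,
        sire_truth=sire_bv,
    )
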