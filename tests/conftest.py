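import numpy as np
import pandas as pd
import pytest

from poolsire import FlockConfig, build_hgrm, simulate_flock
from poolsire.flock import ProgenyTable


@pytest.fixture(scope="session")
def small_config():
    """A reduced flock that keeps unit tests fast but exercises every stage."""
    return FlockConfig(
        n_sires=15,
        n_genotyped_sires=12,
        n_progeny=900,
        n_loci=800,
        max_per_cell=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_flock(small_config):
    return simulate_flock(small_config)


@pytest.fixture(scope="session")
def small_grm(small_flock):
    return build_hgrm(small_flock.sires, small_flock.pools)


def make_progeny(sexes, scores, genotypes=None, sires=None):
    """Hand-built ProgenyTable for pooling/IO tests (truth columns zeroed)."""
    n = len(sexes)
    if genotypes is None:
        genotypes = np.zeros((n, 1), dtype=np.float32)
    genotypes = np.asarray(genotypes, dtype=np.float32)
    ids = pd.Index([f"P{i + 1:04d}" for i in range(n)], name="animal_id")
    table = pd.DataFrame(
        {
            "sire_id": sires if sires is not None else ["S01"] * n,
            "sex": list(sexes),
            "true_bv": 0.0,
            "liability": 0.0,
            "dag_score": list(scores),
        },
        index=ids,
    )
    loci = pd.Index([f"L{j + 1:05d}" for j in range(genotypes.shape[1])], name="locus")
    return ProgenyTable(table=table, genotypes=genotypes, loci=loci)
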