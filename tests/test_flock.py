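"""Simulator behaviour: Hardy-Weinberg sires, Mendelian gene-drop, liability
phenotype, pooling partition and Dirichlet contribution noise."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from poolsire import (
    ConfigError,
    FlockConfig,
    assign_pools,
    pool_baf,
    simulate_flock,
    simulate_progeny,
    simulate_sires,
)
from poolsire.flock import PoolAssignment

from conftest import make_progeny


class TestSimulateSires:
    def test_hardy_weinberg_at_half(self):
        cfg = FlockConfig(n_sires=4000, n_genotyped_sires=4000, n_loci=1,
                          maf_low=0.5, maf_high=0.5)
        calls = simulate_sires(cfg, np.random.default_rng(0)).calls.to_numpy().ravel()
        freqs = [(calls == v).mean() for v in (0.0, 0.5, 1.0)]
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.03)

    def test_fixed_locus_all_reference(self):
        cfg = FlockConfig(n_sires=20, n_genotyped_sires=20, n_loci=5,
                          maf_low=0.0, maf_high=0.0)
        sires = simulate_sires(cfg, np.random.default_rng(0))
        assert (sires.calls.to_numpy() == 0.0).all()

    def test_genotyped_subset_flagged(self):
        cfg = FlockConfig(n_sires=45, n_genotyped_sires=33, n_loci=10)
        sires = simulate_sires(cfg, np.random.default_rng(0))
        assert len(sires.genotyped) == 33
        assert len(sires.genotyped_calls) == 33
        assert sires.calls.shape[0] == 45

    def test_invalid_maf_bounds_rejected(self):
        with pytest.raises(ConfigError):
            FlockConfig(maf_low=0.4, maf_high=0.2)


class TestSimulateProgeny:
    def test_mendelian_consistency_with_sire(self, small_flock):
        """At loci where the sire is homozygous, progeny must carry that allele."""
        sires = small_flock.sires
        prog = small_flock.progeny
        for sid in sires.calls.index[:5]:
            rows = np.flatnonzero((prog.table["sire_id"] == sid).to_numpy())[:20]
            sire_row = sires.calls.loc[sid].to_numpy()
            geno = prog.genotypes[rows].astype(float)
            # sire BAF 0 -> paternal allele 0 -> progeny BAF <= 0.5
            assert (geno[:, sire_row == 0.0] <= 0.5).all()
            assert (geno[:, sire_row == 1.0] >= 0.5).all()

    def test_transmission_slope_half(self):
        """Progeny-mean liability regressed on sire BV has slope ~0.5."""
        cfg = FlockConfig(n_sires=30, n_genotyped_sires=30, n_progeny=10_000,
                          n_loci=500, seed=11)
        rng = np.random.default_rng(cfg.seed)
        sires = simulate_sires(cfg, rng)
        prog, sire_bv = simulate_progeny(sires, cfg, rng)
        means = prog.table.groupby("sire_id")["liability"].mean()
        slope = stats.linregress(sire_bv.loc[means.index], means).slope
        assert 0.4 < slope < 0.6

    def test_zero_heritability_kills_genetic_signal(self):
        cfg = FlockConfig(n_sires=30, n_genotyped_sires=30, n_progeny=6000,
                          n_loci=300, heritability=0.0, seed=3)
        rng = np.random.default_rng(cfg.seed)
        sires = simulate_sires(cfg, rng)
        prog, sire_bv = simulate_progeny(sires, cfg, rng)
        assert np.allclose(sire_bv, 0.0)
        groups = [g["liability"].to_numpy() for _, g in prog.table.groupby("sire_id")]
        assert stats.f_oneway(*groups).pvalue > 1e-3

    def test_full_heritability_score_tracks_bv(self):
        """With h2=1 and one effective cutpoint the score is set by BV alone."""
        cfg = FlockConfig(n_sires=10, n_genotyped_sires=10, n_progeny=500,
                          n_loci=200, heritability=1.0,
                          category_thresholds=(-1e9, 0.0, 1e9, 2e9), seed=5)
        rng = np.random.default_rng(cfg.seed)
        sires = simulate_sires(cfg, rng)
        prog, _ = simulate_progeny(sires, cfg, rng)
        assert set(prog.table["dag_score"]) <= {2, 3}
        assert ((prog.table["dag_score"] == 3) == (prog.table["true_bv"] > 0)).all()

    def test_half_sib_intraclass_correlation(self):
        """Paternal half-sib ICC of liability ~ h2/4."""
        cfg = FlockConfig(n_sires=100, n_genotyped_sires=100, n_progeny=5000,
                          n_loci=400, heritability=0.35, seed=13)
        rng = np.random.default_rng(cfg.seed)
        sires = simulate_sires(cfg, rng)
        prog, _ = simulate_progeny(sires, cfg, rng)
        df = prog.table
        grand = df["liability"].mean()
        groups = df.groupby("sire_id")["liability"]
        k = df.groupby("sire_id").size().mean()
        msb = sum(len(g) * (g.mean() - grand) ** 2 for _, g in groups) / (groups.ngroups - 1)
        msw = sum(((g - g.mean()) ** 2).sum() for _, g in groups) / (len(df) - groups.ngroups)
        icc = (msb - msw) / (msb + (k - 1) * msw)
        assert abs(icc - 0.35 / 4) < 0.03


class TestAssignPools:
    def test_cap_and_replicates(self):
        prog = make_progeny(["male"] * 100, [1] * 100)
        cfg = FlockConfig(max_per_cell=80, n_replicates=2)
        pools = assign_pools(prog, cfg, np.random.default_rng(0))
        assert [p.nominal_size for p in pools] == [40, 40]

    def test_odd_cell_splits_evenly(self):
        prog = make_progeny(["female"] * 66, [5] * 66)
        pools = assign_pools(prog, FlockConfig(), np.random.default_rng(0))
        assert sorted(p.nominal_size for p in pools) == [33, 33]

    def test_partition_within_cells(self, small_flock):
        seen = {}
        for pool in small_flock.assignments:
            for m in pool.members:
                assert m not in seen, "animal assigned to two pools"
                seen[m] = (pool.sex, pool.dag_score)
        table = small_flock.progeny.table
        for m, (sex, score) in seen.items():
            assert table.loc[m, "sex"] == sex
            assert table.loc[m, "dag_score"] == score

    def test_empty_cell_omitted(self, caplog):
        prog = make_progeny(["male"] * 30, [1] * 30)  # no females, no scores 2-5
        with caplog.at_level("WARNING"):
            pools = assign_pools(prog, FlockConfig(), np.random.default_rng(0))
        assert {p.sex for p in pools} == {"male"}
        assert {p.dag_score for p in pools} == {1}
        assert "omitted" in caplog.text


class TestPoolBaf:
    def test_singleton_pool_exact(self):
        geno = np.array([[0.0, 0.5, 1.0]])
        prog = make_progeny(["male"], [1], genotypes=geno)
        pool = PoolAssignment("M1r1", "male", 1, ("P0001",))
        result = pool_baf(prog, [pool], 5.0, np.random.default_rng(0))
        assert np.array_equal(result.baf.to_numpy().ravel(), [0.0, 0.5, 1.0])

    def test_fixed_locus_unaffected_by_weights(self):
        geno = np.ones((4, 2), dtype=np.float32)
        prog = make_progeny(["male"] * 4, [1] * 4, genotypes=geno)
        pool = PoolAssignment("M1r1", "male", 1, tuple(prog.table.index))
        result = pool_baf(prog, [pool], 0.5, np.random.default_rng(1))
        assert np.allclose(result.baf.to_numpy(), 1.0)

    def test_equal_weights_arithmetic_mean(self):
        geno = np.array([[0.0], [0.5], [1.0], [0.5]])
        prog = make_progeny(["male"] * 4, [1] * 4, genotypes=geno)
        pool = PoolAssignment("M1r1", "male", 1, tuple(prog.table.index))
        result = pool_baf(prog, [pool], np.inf, np.random.default_rng(0))
        assert result.baf.iloc[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_convex_combination_bounds(self, small_flock):
        row_pos = pd.Series(
            np.arange(len(small_flock.progeny.table)),
            index=small_flock.progeny.table.index,
        )
        for pool in small_flock.assignments:
            idx = row_pos[list(pool.members)].to_numpy()
            member = small_flock.progeny.genotypes[idx]
            baf = small_flock.pools.baf.loc[pool.pool_id].to_numpy()
            assert (baf >= member.min(axis=0) - 1e-9).all()
            assert (baf <= member.max(axis=0) + 1e-9).all()

    def test_nonpositive_concentration_rejected(self):
        prog = make_progeny(["male"], [1])
        pool = PoolAssignment("M1r1", "male", 1, ("P0001",))
        with pytest.raises(ConfigError):
            pool_baf(prog, [pool], 0.0, np.random.default_rng(0))


class TestReproducibility:
    def test_same_seed_bitwise_identical(self, small_config):
        a = simulate_flock(small_config)
        b = simulate_flock(small_config)
        pd.testing.assert_frame_equal(a.sires.calls, b.sires.calls)
        pd.testing.assert_frame_equal(a.pools.baf, b.pools.baf)
        pd.testing.assert_frame_equal(a.progeny.table, b.progeny.table)
        assert np.array_equal(a.progeny.genotypes, b.progeny.genotypes)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"heritability": 1.5},
            {"n_genotyped_sires": 50, "n_sires": 45},
            {"category_thresholds": (0.0, 0.0, 1.0, 2.0)},
            {"contribution_concentration": -1.0},
            {"retention": "lifo"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            FlockConfig(**kwargs)
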