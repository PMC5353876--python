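import numpy as np
import pytest
from scipy import stats

from perturbnet import (
    PerturbationMatrix,
    SimulationConfig,
    StageNetwork,
    build_stage_network,
    common_network,
    compute_threshold,
    even_grouping,
    group_scores,
    perturbation_scores,
    pooled_edges,
    sample_random_stage_networks,
    select_perturbed,
    significance_test,
    simulate_dataset,
)
from perturbnet.significance import empirical_p_value, parametric_p_value


def net(label, *pairs):
    return StageNetwork(label, frozenset(pairs))


class TestPooledEdges:
    def test_union(self):
        pool = pooled_edges([net("a", ("A", "B"), ("B", "C")), net("b", ("B", "C"), ("C", "D"))])
        assert set(pool) == {("A", "B"), ("B", "C"), ("C", "D")}

    def test_identical_stages(self):
        pool = pooled_edges([net("a", ("A", "B")), net("b", ("A", "B"))])
        assert set(pool) == {("A", "B")}

    def test_disjoint_sizes_add(self):
        a = net("a", ("A", "B"), ("C", "D"))
        b = net("b", ("E", "F"), ("G", "H"), ("I", "J"))
        assert len(pooled_edges([a, b])) == 5

    def test_sorted_deterministic(self):
        pool = pooled_edges([net("a", ("C", "D"), ("A", "B")), net("b", ("A", "B"))])
        assert pool == tuple(sorted(pool))

    def test_empty_pool_error(self):
        with pytest.raises(ValueError, match="empty"):
            pooled_edges([net("a"), net("b")])


class TestSampleRandomStageNetworks:
    def test_exhaustive_draw_returns_pool(self):
        pool = tuple(sorted({("A", "B"), ("B", "C"), ("C", "D")}))
        nets = sample_random_stage_networks(pool, [3, 3], np.random.default_rng(0))
        for sn in nets:
            assert sn.edges == frozenset(pool)

    def test_size_exceeds_pool_error(self):
        with pytest.raises(ValueError, match="pool"):
            sample_random_stage_networks((("A", "B"),), [2], np.random.default_rng(0))

    def test_draw_frequencies_uniform(self):
        pool = tuple((f"a{i}", f"b{i}") for i in range(10))
        rng = np.random.default_rng(123)
        counts = dict.fromkeys(pool, 0)
        for _ in range(10_000):
            (sn,) = sample_random_stage_networks(pool, [1], rng)
            counts[next(iter(sn.edges))] += 1
        gof = stats.chisquare(list(counts.values()))
        assert gof.pvalue > 0.001

    def test_fixed_seed_reproducible(self):
        pool = tuple((f"a{i}", f"b{i}") for i in range(20))
        draws1 = sample_random_stage_networks(pool, [5, 7], np.random.default_rng(42))
        draws2 = sample_random_stage_networks(pool, [5, 7], np.random.default_rng(42))
        assert [d.edges for d in draws1] == [d.edges for d in draws2]


def _strong_signal_case():
    """One edge conserved across every stage with a huge score shift; random
    draws almost never reproduce it in all stages simultaneously."""
    genes = ["A", "B"] + [f"x{i}" for i in range(100)]
    bg_edges = [(f"x{i}", f"x{i+1}") for i in range(0, 98, 2)]
    stage1 = net("s1", ("A", "B"), *bg_edges)
    stage2 = net("s2", ("A", "B"))
    stage3 = net("s3", ("A", "B"))
    stage4 = net("s4", ("A", "B"))
    rng = np.random.default_rng(0)
    scores = rng.normal(scale=0.01, size=(len(genes), 4))
    scores[0] = [10.0, 0.0, 0.0, -10.0]
    scores[1] = [8.0, 0.0, 0.0, -8.0]
    pm = PerturbationMatrix(tuple(genes), ("s1", "s2", "s3", "s4"), scores, grouped=True)
    return [stage1, stage2, stage3, stage4], pm


class TestSignificanceTest:
    def test_empirical_floor(self):
        nets, pm = _strong_signal_case()
        res = significance_test(nets, pm, ("s1", "s4"), n_iter=9999, seed=5)
        assert res.null.values.max() < res.observed  # no null draw reaches the observed
        assert res.p_empirical == pytest.approx(1 / 10_000)

    def test_empirical_p_never_zero(self):
        assert empirical_p_value(np.zeros(100), 1.0) == pytest.approx(1 / 101)

    def test_degenerate_pool_gives_p_one(self):
        # every stage equals the pool -> every random draw equals the pool
        edges = [("A", "B"), ("C", "D")]
        nets = [net("s1", *edges), net("s2", *edges)]
        pm = PerturbationMatrix(
            ("A", "B", "C", "D"), ("s1", "s2"),
            np.array([[1.0, -1.0], [0.5, -0.5], [0.2, -0.2], [0.1, -0.1]]),
            grouped=True,
        )
        res = significance_test(nets, pm, ("s1", "s2"), n_iter=500, seed=1)
        assert res.p_empirical == 1.0
        assert res.null.sd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.null.values, res.observed)

    def test_fixed_seed_bit_reproducible(self):
        nets, pm = _strong_signal_case()
        a = significance_test(nets, pm, ("s1", "s4"), n_iter=300, seed=9)
        b = significance_test(nets, pm, ("s1", "s4"), n_iter=300, seed=9)
        assert a.observed == b.observed
        np.testing.assert_array_equal(a.null.values, b.null.values)
        assert a.p_empirical == b.p_empirical
        np.testing.assert_equal(a.p_parametric, b.p_parametric)  # NaN-safe

    def test_empty_observed_common_error(self):
        nets = [net("s1", ("A", "B")), net("s2", ("C", "D"))]
        pm = PerturbationMatrix(("A", "B", "C", "D"), ("s1", "s2"), np.zeros((4, 2)), grouped=True)
        with pytest.raises(ValueError, match="common network is empty"):
            significance_test(nets, pm, ("s1", "s2"), n_iter=10, seed=0)

    def test_n_iter_validation(self):
        nets, pm = _strong_signal_case()
        with pytest.raises(ValueError, match="n_iter"):
            significance_test(nets, pm, ("s1", "s4"), n_iter=0, seed=0)

    def test_unknown_null_method(self):
        nets, pm = _strong_signal_case()
        with pytest.raises(ValueError, match="null method"):
            significance_test(nets, pm, ("s1", "s4"), n_iter=10, seed=0, null_method="bootstrap")

    def test_empty_intersections_recorded_as_zero(self):
        nets, pm = _strong_signal_case()
        res = significance_test(nets, pm, ("s1", "s4"), n_iter=500, seed=3)
        assert res.null.n_empty > 0
        assert (res.null.values == 0.0).sum() >= res.null.n_empty

    def test_label_permute_null_runs(self):
        nets, pm = _strong_signal_case()
        res = significance_test(nets, pm, ("s1", "s4"), n_iter=400, seed=2,
                                null_method="label-permute")
        assert res.null_method == "label-permute"
        # identity permutation reproduces the observed value, so p is bounded
        # away from the floor
        assert res.p_empirical > 1 / 401


class TestParametricPValue:
    def test_reporting_convention_magnitude(self):
        # a 6-sigma exceedance must come out far below the empirical floor
        # that 10,000 draws could ever resolve
        p = parametric_p_value(0.655, 0.205, 0.075)
        assert p < 1e-8
        assert p == pytest.approx(stats.norm.sf(6.0), rel=1e-9)

    def test_zero_sd_is_nan(self):
        assert np.isnan(parametric_p_value(1.0, 0.5, 0.0))


class TestPooledNullBias:
    def test_pooled_null_is_anticonservative_without_time_structure(self):
        """Characterization, not a correctness claim: with exchangeable
        columns the observed common network over-represents genes with
        extreme scores, while pooled uniform draws do not, so the default
        null yields systematically small p-values.  The label-permute null
        does not share this bias (see the calibration acceptance test)."""
        ps = []
        for seed in range(60):
            cfg = SimulationConfig(
                n_genes=60, n_timepoints=8, module_size=0, module_edges=0,
                amplitude=0.0, noise_sd=1.0, scaffold_edges=150, seed=seed,
            )
            m, scaffold, _ = simulate_dataset(cfg)
            pm = group_scores(perturbation_scores(m), even_grouping(m.time_labels, 4))
            sel = select_perturbed(pm, compute_threshold(pm, 1.0))
            nets = [build_stage_network(sel.genes_for(s), scaffold, s) for s in pm.stage_labels]
            if not common_network(nets).edges:
                continue
            res = significance_test(nets, pm, (pm.stage_labels[0], pm.stage_labels[1]),
                                    n_iter=100, seed=seed + 10_000)
            ps.append(res.p_empirical)
        assert len(ps) > 40
        assert np.mean(ps) < 0.3  # far below the 0.5 of a calibrated test
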