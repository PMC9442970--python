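import numpy as np
import pytest
from scipy import stats

from motifmod.cluster import Module
from motifmod.network import CompositeNetwork, LayerSpec
from motifmod.superview import (
    connectivity_ci,
    count_shared_edges,
    de_gene_set_enrichment,
    module_regulator_specificity,
    module_set_connectivity_test,
    regulator_module_strength,
    regulator_specificity,
    superview_null,
    superview_score,
    superview_table,
)


def _module(name, nodes):
    return Module(name, "COM", set(nodes), [], [])


def _p_net(edges, nodes=()):
    net = CompositeNetwork(layers=[LayerSpec("P", False)])
    for u, v in edges:
        net.add_edge(u, v, "P")
    net.nodes.update(nodes)
    return net


class TestSharedEdgeCounts:
    def test_disjoint_modules_without_crossing_edges(self):
        net = _p_net([("x", "y"), ("u", "v")])
        assert count_shared_edges({"x", "y"}, {"u", "v"}, net, "P") == 0

    def test_internal_edges_not_counted(self):
        net = _p_net([("x", "u"), ("y", "v"), ("x", "y")])
        assert count_shared_edges({"x", "y"}, {"u", "v"}, net, "P") == 2

    def test_directed_crossing_pooled_both_ways(self):
        net = CompositeNetwork(layers=[LayerSpec("R", True)])
        net.add_edge("x", "u", "R")
        net.add_edge("u", "y", "R")
        assert count_shared_edges({"x", "y"}, {"u"}, net, "R") == 2

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(12)]
        edges = {
            tuple(sorted(rng.choice(nodes, 2, replace=False))) for _ in range(20)
        }
        net = _p_net(edges)
        a, b = set(nodes[:4]), set(nodes[4:9])
        assert count_shared_edges(a, b, net, "P") == count_shared_edges(b, a, net, "P")


class TestNullModel:
    def test_empty_layer_null_is_degenerate(self):
        net = _p_net([], nodes=[f"n{i}" for i in range(10)])
        mu, sigma = superview_null(3, 3, net, "P", B=50, seed=0)
        assert (mu, sigma) == (0.0, 0.0)

    def test_complete_layer_null_is_exact(self):
        nodes = [f"n{i}" for i in range(8)]
        net = _p_net([(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]])
        mu, sigma = superview_null(3, 4, net, "P", B=100, seed=0)
        assert mu == pytest.approx(12.0)
        assert sigma == pytest.approx(0.0)

    def test_er_layer_null_matches_analytic_expectation(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i:02d}" for i in range(40)]
        edges = [
            (u, v)
            for i, u in enumerate(nodes)
            for v in nodes[i + 1:]
            if rng.random() < 0.3
        ]
        net = _p_net(edges, nodes)
        density = len(net.edges["P"]) / (40 * 39 / 2)
        mu, sigma = superview_null(5, 5, net, "P", B=2000, seed=1)
        expect = 25 * density
        assert abs(mu - expect) < 3 * sigma / np.sqrt(2000) * 25

    def test_oversized_modules_rejected(self):
        net = _p_net([("a", "b")])
        with pytest.raises(ValueError):
            superview_null(2, 2, net, "P")


class TestScore:
    def test_observed_at_mean(self):
        z, p = superview_score(5, 5.0, 2.0)
        assert (z, p) == (0.0, 0.5)

    def test_no_interactions_rule(self):
        assert superview_score(0, 3.0, 1.0) == (0.0, 1.0)

    def test_normal_quantile(self):
        z, p = superview_score(13, 10.0, 2.0)
        assert z == pytest.approx(1.5)
        assert p == pytest.approx(1 - stats.norm.cdf(1.5))

    def test_degenerate_sigma_is_capped(self):
        z, p = superview_score(4, 1.0, 0.0)
        assert z == 1e6 and p == pytest.approx(0.0)


class TestRegulatorStatistics:
    def _reg_net(self):
        net = CompositeNetwork(layers=[LayerSpec("R", True), LayerSpec("P", False)])
        for t in ["g1", "g2", "g3"]:
            net.add_edge("tf", t, "R")
        net.nodes.update({"g4", "g5", "g6"})
        return net

    def test_strength_fraction(self):
        net = self._reg_net()
        m = _module("M1", ["g1", "g2", "g3", "g4", "g5", "g6"])
        assert regulator_module_strength("tf", m, net, "R") == pytest.approx(0.5)

    def test_strength_no_edges(self):
        net = self._reg_net()
        m = _module("M1", ["g4", "g5", "g6", "g7", "g8"])
        assert regulator_module_strength("tf", m, net, "R") == 0.0

    def test_strength_full_coverage(self):
        net = CompositeNetwork(layers=[LayerSpec("M", True)])
        for t in [f"g{i}" for i in range(5)]:
            net.add_edge("hsa-miR-1", t, "M")
        m = _module("M1", [f"g{i}" for i in range(5)])
        assert regulator_module_strength("hsa-miR-1", m, net, "M") == 1.0

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError):
            regulator_module_strength("tf", _module("M", []), self._reg_net(), "R")

    def test_module_specificity_fraction(self):
        # 33 of 526 TFs target the module
        net = CompositeNetwork(layers=[LayerSpec("R", True)])
        for k in range(526):
            tgt = "inmod" if k < 33 else "outside"
            net.add_edge(f"tf{k:03d}", tgt, "R")
        m = _module("M1", ["inmod", "other1", "other2", "other3", "other4"])
        regs = {"R": {f"tf{k:03d}" for k in range(526)}}
        val = module_regulator_specificity(m, regs, net)
        assert val == pytest.approx(33 / 526)

    def test_regulator_specificity(self):
        net = CompositeNetwork(layers=[LayerSpec("R", True)])
        net.add_edge("tf", "g0", "R")
        modules = [_module(f"M{i}", [f"g{i}"]) for i in range(100)]
        assert regulator_specificity("tf", modules, net) == pytest.approx(0.01)
        # master regulator hitting 46 of 100 modules
        for i in range(1, 46):
            net.add_edge("tf", f"g{i}", "R")
        assert regulator_specificity("tf", modules, net) == pytest.approx(0.46)
        assert regulator_specificity("silent", modules, net) == 0.0


class TestCalibrationAndTable:
    def test_superview_table_pvalues_calibrated_on_random_modules(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i:02d}" for i in range(60)]
        edges = [
            (u, v)
            for i, u in enumerate(nodes)
            for v in nodes[i + 1:]
            if rng.random() < 0.25
        ]
        net = _p_net(edges, nodes)
        modules = []
        for k in range(14):
            pick = rng.choice(nodes, size=8, replace=False)
            modules.append(_module(f"M{k}", pick))
        table = superview_table(modules, net, B=400, seed=0)
        rate = float((table.p < 0.05).mean())
        assert 0.0 <= rate < 0.15  # near-nominal for random modules

    def test_record_invariants(self, planted_fixture):
        mods = planted_fixture["modules"][:6]
        table = superview_table(mods, planted_fixture["net"], B=100, seed=0)
        zero = table[table.x == 0]
        assert (zero.z == 0).all() and (zero.p == 1).all()
        assert table.p.between(0, 1).all()
        # one record per unordered pair per layer
        n_layers = len(planted_fixture["net"].letters)
        assert len(table) == n_layers * len(mods) * (len(mods) - 1) // 2


class TestModuleSetConnectivity:
    def test_ci_reconstruction(self):
        lo, hi = connectivity_ci(1720, 880, 1000)
        assert lo == pytest.approx(1665, abs=1)
        assert hi == pytest.approx(1774, abs=1)
        assert 32038 / hi == pytest.approx(18, abs=0.2)

    def test_whole_universe_fold_change_near_one(self, planted_fixture):
        mods = planted_fixture["modules"]
        table = superview_table(mods, planted_fixture["net"], B=50, seed=0)
        res = module_set_connectivity_test(
            {m.name for m in mods}, table, B=50, seed=1
        )
        total = res[res.layer == "Total"].iloc[0]
        if total.observed > 0:
            assert total.fold_change == pytest.approx(1.0, abs=0.05)

    def test_unconnected_selection_observed_zero(self):
        # three island modules plus one well-connected pair: selecting the
        # islands yields zero observed crossings
        net = _p_net([])
        mods = []
        for k in range(3):
            nodes = [f"m{k}_{i}" for i in range(5)]
            for i in range(4):
                net.add_edge(nodes[i], nodes[i + 1], "P")
            mods.append(_module(f"ISL{k}", nodes))
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        for u in a:
            for v in b:
                net.add_edge(u, v, "P")
        mods += [_module("HUB_A", a), _module("HUB_B", b)]
        table = superview_table(mods, net, B=50, seed=0)
        res = module_set_connectivity_test(
            {"ISL0", "ISL1", "ISL2"}, table, B=50, seed=2
        )
        total = res[res.layer == "Total"].iloc[0]
        assert total.observed == 0
        assert total.fold_change == 0.0


class TestDEEnrichment:
    def test_equal_rates_give_unit_fold(self):
        sel = [_module("A", [f"a{i}" for i in range(10)])]
        rest = [_module("B", [f"b{i}" for i in range(10)])]
        de = {"a0", "a1", "b0", "b1"}
        fold, p = de_gene_set_enrichment(sel, sel + rest, de)
        assert fold == pytest.approx(1.0)

    def test_maximal_enrichment(self):
        sel = [_module("A", [f"a{i}" for i in range(5)])]
        rest = [_module("B", [f"b{i}" for i in range(20)])]
        de = {f"a{i}" for i in range(5)}
        fold, p = de_gene_set_enrichment(sel, sel + rest, de)
        assert fold == float("inf")
        assert p == pytest.approx(stats.hypergeom.sf(4, 25, 5, 5))

    def test_hand_computed_example(self):
        sel = [_module("A", [f"a{i}" for i in range(20)])]
        rest = [_module("B", [f"b{i}" for i in range(1000)])]
        de = {f"a{i}" for i in range(10)} | {f"b{i}" for i in range(50)}
        fold, p = de_gene_set_enrichment(sel, sel + rest, de)
        assert fold == pytest.approx((10 / 20) / (50 / 1000))
        assert p == pytest.approx(stats.hypergeom.sf(9, 1020, 60, 20))
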