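import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import linregress

from trireg.network import (
    Edge,
    FilterSpec,
    NetworkError,
    RegulatoryNetwork,
    degree_preserving_randomize,
    fit_power_law,
    merge_networks,
    read_edge_table,
    read_network,
    subnetwork,
    topology_summary,
    write_network,
)
from trireg.synthetic import GeneratorConfig, generate_network

from .conftest import random_typed_network


def _write_tsv(path, rows, header="source\ttarget\tsupport"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path


class TestReadEdgeTable:
    def test_support_count_filter_is_strict(self, tmp_path):
        """'more than 20 datasets' keeps 21 and drops exactly 20."""
        p = _write_tsv(tmp_path / "e.tsv", ["TFA\tLNC1\t20", "TFA\tLNC2\t21"])
        edges = read_edge_table(p, "TF->lncRNA", FilterSpec("support_count", 20))
        assert {e.target for e in edges} == {"LNC2"}

    def test_support_score_filter_is_inclusive(self, tmp_path):
        """Prediction-score cutoff keeps 0.95 itself and drops 0.949."""
        p = _write_tsv(tmp_path / "e.tsv", ["M1\tLNC1\t0.95", "M1\tLNC2\t0.949"])
        edges = read_edge_table(p, "miRNA->lncRNA", FilterSpec("support_score", 0.95))
        assert {e.target for e in edges} == {"LNC1"}

    def test_empty_table(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", [], header="source\ttarget")
        assert read_edge_table(p, "TF->miRNA") == set()

    def test_malformed_row_names_line(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", ["TFA\tM1", "\tM2"],
                       header="source\ttarget")
        with pytest.raises(NetworkError, match="line 3"):
            read_edge_table(p, "TF->miRNA")

    def test_unknown_relation_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "e.tsv", ["A\tB"], header="source\ttarget")
        with pytest.raises(NetworkError, match="unknown relation"):
            read_edge_table(p, "lncRNA->miRNA")

    def test_self_edge_rejected(self, tmp_path):
        with pytest.raises(NetworkError, match="self-edge"):
            Edge("X", "X", "TF->miRNA")


class TestMerge:
    def _sets(self):
        e1 = Edge("TFA", "M1", "TF->miRNA")
        e2 = Edge("TFA", "M2", "TF->miRNA")
        e3 = Edge("M1", "TFB", "miRNA->TF")
        return {e1, e2, e3}, {e1}

    def test_union_and_intersection(self):
        s1, s2 = self._sets()
        assert len(merge_networks([s1, s2], "union").edges) == 3
        assert len(merge_networks([s1, s2], "intersection").edges) == 1

    def test_single_set_identity(self):
        s1, _ = self._sets()
        net = merge_networks([s1])
        assert {e.key for e in net.edges} == {e.key for e in s1}

    def test_kind_conflict_lists_ids(self):
        s1 = {Edge("TFA", "M1", "TF->miRNA")}      # TFA is a TF
        s2 = {Edge("TFA", "TFB", "lncRNA->TF")}    # TFA claimed as lncRNA
        with pytest.raises(NetworkError, match="TFA"):
            merge_networks([s1, s2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["TFA", "TFB", "TFC"]),
                  st.sampled_from(["M1", "M2", "M3"])),
        min_size=1, max_size=8,
    ))
    def test_union_idempotent_and_commutative(self, pairs):
        s = {Edge(a, b, "TF->miRNA") for a, b in pairs}
        t = {Edge("TFA", "M1", "TF->miRNA")}
        ab = merge_networks([s, t], "union")
        ba = merge_networks([t, s], "union")
        twice = merge_networks([s, s, t], "union")
        assert ab == ba == twice


class TestSubnetwork:
    def test_all_kinds_is_identity(self, small_bundle):
        net = small_bundle.network
        sub = subnetwork(net, ["TF", "miRNA", "lncRNA"])
        assert sub == net
        assert sub.node_order == net.node_order

    def test_induced_edges_and_isolated_nodes(self):
        net = RegulatoryNetwork({
            Edge("TFA", "M1", "TF->miRNA"),
            Edge("M1", "L1", "miRNA->lncRNA"),
        })
        sub = subnetwork(net, ["miRNA", "lncRNA"])
        assert {e.key for e in sub.edges} == {("M1", "L1", "miRNA->lncRNA")}
        assert set(sub.node_order) == {"M1", "L1"}  # TF dropped, others kept
        # an lncRNA with no surviving edges is retained as isolated
        net2 = RegulatoryNetwork({Edge("TFA", "M1", "TF->miRNA")},
                                 extra_nodes={"L9": "lncRNA"})
        sub2 = subnetwork(net2, ["miRNA", "lncRNA"])
        assert set(sub2.node_order) == {"M1", "L9"}

    def test_empty_kinds_rejected(self, small_bundle):
        with pytest.raises(NetworkError):
            subnetwork(small_bundle.network, [])


class TestTopology:
    def test_star_graph(self):
        net = RegulatoryNetwork(
            {Edge("TFH", f"M{i}", "TF->miRNA") for i in range(5)}
        )
        ts = topology_summary(net)
        assert ts.degree["TFH"] == 5
        assert all(ts.degree[f"M{i}"] == 1 for i in range(5))
        assert ts.degree_one_fraction == pytest.approx(5 / 6)

    def test_histogram_and_degree_sums(self, small_bundle):
        net = small_bundle.network
        ts = topology_summary(net)
        assert int(ts.degree_histogram().sum()) == len(net)
        assert ts.in_degree.sum() == ts.out_degree.sum() == len(net.edges)
        assert (ts.degree == ts.in_degree + ts.out_degree).all()

    def test_powerlaw_matches_independent_regression(self, small_bundle):
        """OLS fit agrees with scipy.stats.linregress re-fit to 1e-10."""
        deg = topology_summary(small_bundle.network).degree.to_numpy()
        fit = fit_power_law(deg)
        assert fit is not None and fit.b < 0
        vals, counts = np.unique(deg[deg > 0], return_counts=True)
        ref = linregress(np.log10(vals), np.log10(counts))
        assert fit.b == pytest.approx(ref.slope, abs=1e-10)
        assert np.log10(fit.a) == pytest.approx(ref.intercept, abs=1e-10)
        assert fit.r2 == pytest.approx(ref.rvalue ** 2, abs=1e-10)

    def test_fit_absent_when_degenerate(self):
        net = RegulatoryNetwork({Edge("TFA", "M1", "TF->miRNA")})
        ts = topology_summary(net)
        assert ts.fits["degree"] is None  # every node has degree 1

    def test_kind_medians_present(self, small_bundle):
        ts = topology_summary(small_bundle.network)
        assert set(ts.kind_medians.index) <= {"TF", "miRNA", "lncRNA"}
        assert {"in_degree", "out_degree"} == set(ts.kind_medians.columns)


class TestRandomize:
    def test_zero_swaps_is_identity(self, small_bundle):
        net = small_bundle.network
        out = degree_preserving_randomize(net, n_swaps=0, rng=0)
        assert out == net

    def test_two_edge_class_single_swap(self):
        """The only legal swap of {a->b, c->d} is {a->d, c->b}."""
        net = RegulatoryNetwork({
            Edge("TFA", "M1", "TF->miRNA"),
            Edge("TFB", "M2", "TF->miRNA"),
        })
        swapped_keys = {("TFA", "M2", "TF->miRNA"), ("TFB", "M1", "TF->miRNA")}
        original_keys = {e.key for e in net.edges}
        seen_swap = False
        for seed in range(20):
            out = degree_preserving_randomize(net, n_swaps=1, rng=seed)
            keys = {e.key for e in out.edges}
            assert keys in (original_keys, swapped_keys)
            seen_swap |= keys == swapped_keys
        assert seen_swap

    def test_degrees_conserved_per_relation_class(self):
        cfg = GeneratorConfig(n_tf=10, n_mirna=30, n_lncrna=60, n_edges=200,
                              module_size=10, n_seeds=5, rng_seed=3)
        net, _ = generate_network(cfg)
        def class_degrees(n):
            d = {}
            for e in n.edges:
                d.setdefault((e.relation, e.source, "out"), 0)
                d[(e.relation, e.source, "out")] += 1
                d.setdefault((e.relation, e.target, "in"), 0)
                d[(e.relation, e.target, "in")] += 1
            return d
        ref = class_degrees(net)
        rng = np.random.default_rng(42)
        for _ in range(100):
            out = degree_preserving_randomize(net, rng=rng)
            assert class_degrees(out) == ref
            assert out.edge_counts_by_relation() == net.edge_counts_by_relation()

    def test_small_class_left_unchanged(self):
        net = RegulatoryNetwork({Edge("TFA", "M1", "TF->miRNA")})
        out = degree_preserving_randomize(net, n_swaps=50, rng=0)
        assert out == net


def test_network_serialization_roundtrip(tmp_path, small_bundle):
    path = tmp_path / "net.tsv"
    write_network(small_bundle.network, path)
    back = read_network(path)
    assert {e.key for e in back.edges} == {e.key for e in small_bundle.network.edges}
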