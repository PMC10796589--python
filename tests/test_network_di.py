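"""Network construction, JI/OCE similarity and the DI-gene rule."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinet.errors import ConsistencyError, ParameterError
from dinet.io_formats import (
    ExpressionTable,
    GenomicInterval,
    InteractionCall,
    PipelineConfig,
)
from dinet.network_di import (
    build_network,
    build_network_pair,
    call_di_genes,
    merge_intervals,
    node_similarity,
    node_similarity_per_replicate,
)


def _call(gene, start, end, condition, replicate=1, pairs=5, adj_p=1e-4, cell="CMK"):
    return InteractionCall(
        anchor_id=f"p_{gene}",
        anchor_kind="promoter",
        gene=gene,
        distal=GenomicInterval("chr1", start, end),
        supporting_pairs=pairs,
        adj_p=adj_p,
        cell_line=cell,
        condition=condition,
        replicate=replicate,
    )


def _graph(edges, pir_coords=None):
    """Tiny network: nodes starting with 'e' are PIRs, others promoters."""
    g = nx.Graph()
    coords = pir_coords or {}
    for u, v in edges:
        for node in (u, v):
            if node.startswith("e"):
                i = coords.get(node, int(node[1:]))
                g.add_node(node, kind="pir", chrom="chr1", start=i * 1000, end=i * 1000 + 500)
            else:
                g.add_node(node, kind="promoter", gene=node)
        g.add_edge(u, v)
    return g


class TestBuildNetwork:
    def test_single_replicate_call_creates_edge(self):
        calls = [_call("G1", 1000, 1500, "none", replicate=1)]
        net = build_network(calls, "CMK", "none")
        assert net.number_of_edges() == 1

    def test_low_support_excluded(self):
        calls = [
            _call("G1", 1000, 1500, "none", replicate=1, pairs=3),
            _call("G1", 1000, 1500, "none", replicate=2, pairs=3),
        ]
        assert build_network(calls, "CMK", "none").number_of_edges() == 0

    def test_adj_p_network_threshold(self):
        calls = [_call("G1", 1000, 1500, "none", adj_p=0.005)]  # passes 0.01, not 0.001
        assert build_network(calls, "CMK", "none").number_of_edges() == 0

    def test_empty_calls_empty_network(self):
        assert build_network([], "CMK", "none").number_of_edges() == 0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError):
            build_network([], "CMK", "cisplatin")

    def test_overlapping_distals_merge_to_one_pir(self):
        calls = [
            _call("G1", 1000, 1500, "none"),
            _call("G2", 1400, 1900, "none"),
        ]
        net = build_network(calls, "CMK", "none")
        pirs = [n for n, d in net.nodes(data=True) if d["kind"] == "pir"]
        assert pirs == ["pir:chr1:1000-1900"]
        assert net.degree[pirs[0]] == 2

    def test_pair_building_shares_pir_namespace(self):
        # the same enhancer shifted by a few bp across conditions is one node
        calls = [
            _call("G1", 1000, 1860, "none"),
            _call("G1", 1010, 1870, "carboplatin"),
        ]
        net_a, net_b = build_network_pair(calls, "CMK", "none", "carboplatin")
        pir_a = {n for n, d in net_a.nodes(data=True) if d["kind"] == "pir"}
        pir_b = {n for n, d in net_b.nodes(data=True) if d["kind"] == "pir"}
        assert pir_a == pir_b

    def test_merge_intervals_union(self):
        merged = merge_intervals(
            [
                GenomicInterval("chr1", 0, 10),
                GenomicInterval("chr1", 5, 20),
                GenomicInterval("chr1", 20, 30),  # touching stays separate
            ]
        )
        assert merged == [GenomicInterval("chr1", 0, 20), GenomicInterval("chr1", 20, 30)]


class TestNodeSimilarity:
    def test_lost_one_of_two_neighbors(self):
        # neighbor sets {e1, e2} vs {e1}: JI = 0.5 but OCE = 1
        net_a = _graph([("x", "e1"), ("x", "e2")])
        net_b = _graph([("x", "e1")])
        sims = node_similarity(net_a, net_b).set_index("node")
        assert sims.loc["x", "ji"] == 0.5
        assert sims.loc["x", "oce"] == 1.0

    def test_identical_neighborhoods(self):
        net = _graph([("x", "e1"), ("x", "e2")])
        sims = node_similarity(net, net).set_index("node")
        assert sims.loc["x", "ji"] == 1.0 and sims.loc["x", "oce"] == 1.0

    def test_partial_overlap(self):
        # {e1,e2,e3} vs {e2,e3,e4} -> JI = 2/4, OCE = 2/3
        net_a = _graph([("x", "e1"), ("x", "e2"), ("x", "e3")])
        net_b = _graph([("x", "e2"), ("x", "e3"), ("x", "e4")])
        sims = node_similarity(net_a, net_b).set_index("node")
        assert sims.loc["x", "ji"] == 0.5
        assert sims.loc["x", "oce"] == pytest.approx(2 / 3)

    def test_absent_node_has_undefined_oce(self):
        net_a = _graph([("x", "e1")])
        net_b = _graph([("y", "e1")])
        sims = node_similarity(net_a, net_b).set_index("node")
        assert sims.loc["x", "ji"] == 0.0
        assert np.isnan(sims.loc["x", "oce"])

    def test_mismatched_pir_namespaces_rejected(self):
        net_a = _graph([("x", "e1")])
        net_b = _graph([("x", "e9")], pir_coords={"e9": 1})  # overlaps e1's interval
        with pytest.raises(ConsistencyError):
            node_similarity(net_a, net_b)

    def test_oracle_equivalence_random_graphs(self):
        # brute force: adjacency from raw edge lists, common neighbors by loop
        rng = np.random.default_rng(42)
        for _ in range(25):
            promoters = [f"p{i}" for i in range(rng.integers(2, 6))]
            pirs = [f"e{i}" for i in range(rng.integers(2, 12))]
            def random_edges():
                return [
                    (p, e)
                    for p in promoters
                    for e in pirs
                    if rng.random() < 0.4
                ]
            ea, eb = random_edges(), random_edges()
            sims = node_similarity(_graph(ea), _graph(eb))
            for row in sims.itertuples(index=False):
                na = [v for u, v in ea if u == row.node] + [u for u, v in ea if v == row.node]
                nb = [v for u, v in eb if u == row.node] + [u for u, v in eb if v == row.node]
                common = sum(1 for n in set(na) if n in nb)
                union = len(set(na) | set(nb))
                assert row.ji == pytest.approx(common / union)
                if min(len(set(na)), len(set(nb))) > 0:
                    assert row.oce == pytest.approx(common / min(len(set(na)), len(set(nb))))
                else:
                    assert np.isnan(row.oce)

    @settings(max_examples=60, derandomize=True)
    @given(
        na=st.sets(st.integers(0, 9), min_size=0, max_size=8),
        nb=st.sets(st.integers(0, 9), min_size=0, max_size=8),
    )
    def test_bounds_symmetry_and_oce_dominates_ji(self, na, nb):
        if not na and not nb:
            return
        net_a = _graph([("x", f"e{i}") for i in na])
        net_b = _graph([("x", f"e{i}") for i in nb])
        fwd = node_similarity(net_a, net_b).set_index("node").loc["x"]
        rev = node_similarity(net_b, net_a).set_index("node").loc["x"]
        assert 0.0 <= fwd.ji <= 1.0
        assert fwd.ji == rev.ji
        if not np.isnan(fwd.oce):
            assert fwd.ji <= fwd.oce <= 1.0
            assert fwd.oce == rev.oce
            if fwd.ji == 1.0:
                assert fwd.oce == 1.0

    def test_shared_edge_addition_never_decreases_ji(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            na = set(rng.choice(10, size=rng.integers(1, 6), replace=False))
            nb = set(rng.choice(10, size=rng.integers(1, 6), replace=False))
            new = int(rng.integers(10, 15))  # neighbor absent from both
            before = node_similarity(
                _graph([("x", f"e{i}") for i in na]),
                _graph([("x", f"e{i}") for i in nb]),
            ).set_index("node").loc["x", "ji"]
            after = node_similarity(
                _graph([("x", f"e{i}") for i in na | {new}]),
                _graph([("x", f"e{i}") for i in nb | {new}]),
            ).set_index("node").loc["x", "ji"]
            assert after >= before


def _expression(tpm_by_gene, cell="CMK"):
    samples = [f"{cell}_none_1", f"{cell}_none_2", f"{cell}_carboplatin_1", f"{cell}_carboplatin_2"]
    df = pd.DataFrame(
        {s: list(tpm_by_gene.values()) for s in samples},
        index=list(tpm_by_gene),
    )
    return ExpressionTable(df)


class TestDiRule:
    def _sims(self, rows):
        return pd.DataFrame(
            rows, columns=["node", "kind", "gene", "deg_a", "deg_b", "n_common", "ji", "oce"]
        )

    def test_rule_combinations(self):
        sims = self._sims(
            [
                ("gene:A", "promoter", "A", 2, 2, 1, 0.5, 0.5),   # DI
                ("gene:B", "promoter", "B", 1, 1, 0, 0.0, 0.0),   # JI = 0 excluded
                ("gene:C", "promoter", "C", 5, 2, 2, 0.4, 1.0),   # OCE = 1 excluded
                ("gene:D", "promoter", "D", 3, 3, 2, 0.6, 0.67),  # JI above max
                ("gene:E", "promoter", "E", 2, 2, 1, 0.5, 0.5),   # not expressed
                ("pir:chr1:0-10", "pir", "", 2, 2, 1, 0.5, 0.5),  # not a promoter
            ]
        )
        expr = _expression({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0, "E": 0.1})
        out = call_di_genes(sims, expr, "CMK", ("none", "carboplatin")).set_index("gene")
        assert out.loc["A", "is_di"]
        assert not out.loc["B", "is_di"] and out.loc["B", "reason"] == "ji_zero"
        assert not out.loc["C", "is_di"] and "oce_one" in out.loc["C", "reason"]
        assert not out.loc["D", "is_di"] and "ji_above_max" in out.loc["D", "reason"]
        assert not out.loc["E", "is_di"] and "not_expressed" in out.loc["E", "reason"]
        assert "pir:chr1:0-10" not in out.index and len(out) == 5

    def test_boundary_ji_exactly_half_is_di(self):
        sims = self._sims([("gene:A", "promoter", "A", 2, 1, 1, 0.5, 1.0)])
        expr = _expression({"A": 5.0})
        out = call_di_genes(sims, expr, "CMK", ("none", "carboplatin"))
        # OCE = 1 blocks the call even though JI <= 0.5
        assert not out["is_di"].iloc[0]

    def test_gene_missing_from_expression_treated_as_zero(self, caplog):
        sims = self._sims([("gene:Z", "promoter", "Z", 2, 2, 1, 0.5, 0.5)])
        expr = _expression({"A": 5.0})
        out = call_di_genes(sims, expr, "CMK", ("none", "carboplatin"))
        assert not out["is_di"].iloc[0]
        assert out["mean_tpm"].iloc[0] == 0.0

    def test_invariant_di_implies_rule(self, default_run):
        cfg = PipelineConfig()
        di = default_run.comparison.di_calls
        called = di[di["is_di"]]
        assert (called["oce"] < 1).all()
        assert ((called["ji"] > 0) & (called["ji"] <= cfg.ji_max)).all()
        assert (called["mean_tpm"] > cfg.tpm_min).all()


class TestPerReplicateMode:
    def test_averaged_similarity_in_bounds(self):
        calls = [_call("G1", 1000, 1500, "none", replicate=r) for r in (1, 2)]
        calls.append(_call("G1", 5000, 5500, "none", replicate=1))
        calls += [_call("G1", 1000, 1500, "carboplatin", replicate=r) for r in (1, 2)]
        sims = node_similarity_per_replicate(calls, "CMK", "none", "carboplatin")
        g1 = sims[sims["gene"] == "G1"]
        assert len(g1) == 1
        assert 0.0 <= g1["ji"].iloc[0] <= 1.0
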