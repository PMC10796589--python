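"""Variant-PIR-gene linking and the Fisher-exact enrichment computations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from dinet.errors import ParameterError
from dinet.integrate_enrich import (
    adjust_pvalues,
    di_enrichment,
    gene_set_enrichment,
    interval_enrichment,
    overlap_variants_pirs,
    variant_gene_links,
)
from dinet.io_formats import GenomicInterval, PipelineConfig, VariantRecord


def fisher_two_sided_enumeration(table):
    """Independent oracle: sum hypergeometric pmf over tables with fixed
    margins whose probability does not exceed the observed table's."""
    a, b = table[0]
    c, d = table[1]
    n, r1, c1 = a + b + c + d, a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    observed = pmf[a - lo]
    return float(min(pmf[pmf <= observed * (1 + 1e-7)].sum(), 1.0))


def _network(edges):
    g = nx.Graph()
    for gene, (start, end) in edges:
        pir = f"pir:chr1:{start}-{end}"
        g.add_node(f"gene:{gene}", kind="promoter", gene=gene)
        g.add_node(pir, kind="pir", chrom="chr1", start=start, end=end)
        g.add_edge(f"gene:{gene}", pir)
    return g


def _variant(vid, pos):
    return VariantRecord(vid, GenomicInterval("chr1", pos, pos + 1), "A", "G")


class TestOverlap:
    def test_half_open_boundaries(self):
        net = _network([("G1", (100, 200))])
        links = overlap_variants_pirs(
            [_variant("at_start", 100), _variant("at_end", 200)], net
        )
        assert len(links["at_start"]) == 1
        assert links["at_end"] == []

    def test_two_adjacent_promoters_give_two_genes(self):
        net = _network([("G1", (100, 200)), ("G2", (100, 200))])
        links = overlap_variants_pirs([_variant("v", 150)], net)
        (pir, genes), = links["v"]
        assert genes == ("G1", "G2")
        assert variant_gene_links(links) == {"v": {"G1", "G2"}}

    def test_variant_outside_all_pirs(self):
        net = _network([("G1", (100, 200))])
        assert overlap_variants_pirs([_variant("v", 5000)], net)["v"] == []


def _di_calls(di_status):
    return pd.DataFrame(
        {"gene": list(di_status), "is_di": list(di_status.values())}
    )


class TestDiEnrichment:
    def test_equal_fractions_odds_ratio_one(self):
        di = {f"C{i}": i < 5 for i in range(50)}
        di.update({f"R{i}": i < 5 for i in range(50)})
        links = {"vc": {f"C{i}" for i in range(50)}, "vr": {f"R{i}" for i in range(50)}}
        res = di_enrichment(links, {"vc"}, _di_calls(di))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.extra["di_fraction_candidate"] == res.extra["di_fraction_rest"]

    def test_p_matches_enumeration_oracle(self):
        # groups sized to give the table [[9,1],[1,9]]
        di = {f"C{i}": i < 9 for i in range(10)}
        di.update({f"R{i}": i < 1 for i in range(10)})
        links = {"vc": {f"C{i}" for i in range(10)}, "vr": {f"R{i}" for i in range(10)}}
        res = di_enrichment(links, {"vc"}, _di_calls(di))
        assert res.table.tolist() == [[9, 1], [1, 9]]
        assert res.p_value == pytest.approx(fisher_two_sided_enumeration(res.table))

    def test_dominance_rule_candidate_wins(self):
        di = {"G1": True, "G2": False}
        links = {"vc": {"G1"}, "vr": {"G1", "G2"}}
        res = di_enrichment(links, {"vc"}, _di_calls(di))
        assert res.extra["n_candidate"] == 1 and res.extra["n_rest"] == 1

    def test_empty_group_not_computable(self):
        res = di_enrichment({"vc": {"G1"}}, {"vc"}, _di_calls({"G1": True}))
        assert not res.computable and res.p_value is None

    def test_relabeling_invariance(self):
        di = {f"g{i}": i % 3 == 0 for i in range(12)}
        links = {
            "v1": {"g0", "g1"}, "v2": {"g2", "g3"},
            "v3": {"g4", "g5", "g6"}, "v4": {"g7", "g8", "g9", "g10", "g11"},
        }
        res1 = di_enrichment(links, {"v1", "v3"}, _di_calls(di))
        remap = {f"g{i}": f"x{i + 100}" for i in range(12)}
        di2 = {remap[g]: s for g, s in di.items()}
        links2 = {f"w{k}": {remap[g] for g in v} for k, v in links.items()}
        res2 = di_enrichment(links2, {"wv1", "wv3"}, _di_calls(di2))
        assert res1.table.tolist() == res2.table.tolist()
        assert res1.p_value == pytest.approx(res2.p_value)

    def test_planted_enrichment_detected(self, default_run):
        res = default_run.enrichment
        assert res.extra["di_fraction_candidate"] > res.extra["di_fraction_rest"]
        assert res.p_value < 0.05

    def test_pair_level_mode(self):
        di = {"G1": True, "G2": False}
        links = {"vc": {"G1", "G2"}, "vr": {"G2"}}
        cfg = PipelineConfig(pair_level_enrichment=True)
        res = di_enrichment(links, {"vc"}, _di_calls(di), cfg)
        assert res.extra["unit"] == "pairs"
        assert res.extra["n_candidate"] == 2


class TestGeneSetEnrichment:
    def test_query_equals_trait_half_universe(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(50)}
        res = gene_set_enrichment(query, query, universe)
        assert res.fold_enrichment == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_disjoint_query_and_trait(self):
        universe = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(10)}
        trait = {f"g{i}" for i in range(20, 30)}
        res = gene_set_enrichment(query, trait, universe)
        assert res.fold_enrichment == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_trait_equals_universe(self):
        universe = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(5)}
        res = gene_set_enrichment(query, universe, universe)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ParameterError):
            gene_set_enrichment({"a"}, {"a"}, {"b"})

    def test_p_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(60)}
        trait = {f"g{i}" for i in range(20)}
        pvals = []
        for k in range(0, 11):
            # |query| fixed at 10 with k trait genes and 10-k non-trait genes
            query = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(30, 40 - k)}
            pvals.append(gene_set_enrichment(query, trait, universe).p_value)
        assert pvals == sorted(pvals, reverse=True)


class TestIntervalEnrichment:
    def _iv(self, start, end):
        return GenomicInterval("chr1", start, end)

    def test_full_coverage_gives_fold_one(self):
        query = [self._iv(10, 20), self._iv(100, 150), self._iv(300, 350)]
        annotation = [self._iv(0, 1000)]
        res = interval_enrichment(query, annotation, 1000)
        assert res.table[0, 0] == len(query)
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_zero_overlap_zero_fold(self):
        res = interval_enrichment(
            [self._iv(0, 10)], [self._iv(500, 600)], 10_000
        )
        assert res.fold_enrichment == 0.0

    def test_fold_arithmetic(self):
        # 3 query intervals, 2 overlapping; annotation covers 10% of genome
        query = [self._iv(0, 10), self._iv(100, 110), self._iv(5000, 5010)]
        annotation = [self._iv(5, 505), self._iv(9000, 9500)]
        res = interval_enrichment(query, annotation, 10_000)
        assert res.fold_enrichment == pytest.approx((2 / 3) / 0.10)

    def test_genome_too_small_rejected(self):
        with pytest.raises(ParameterError):
            interval_enrichment([self._iv(0, 900)], [self._iv(0, 500)], 800)

    def test_merging_before_counting(self):
        # two overlapping query intervals count once after merging
        query = [self._iv(0, 100), self._iv(50, 150)]
        annotation = [self._iv(90, 95)]
        res = interval_enrichment(query, annotation, 100_000)
        assert res.extra["n_query_merged"] == 1
        assert res.table[0, 0] == 1


class TestMultipleTesting:
    def test_bh_adjustment_orders_preserved(self):
        raw = [0.001, 0.01, 0.2, 0.04]
        adj = adjust_pvalues(raw)
        assert (adj >= np.array(raw) - 1e-12).all()
        assert adj.argsort().tolist() == np.array(raw).argsort().tolist()
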