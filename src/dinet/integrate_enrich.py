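"""Variant-to-gene assignment and the three enrichment computations.

* :func:`overlap_variants_pirs` — assign variants to merged PIR nodes and,
  through the network, to the promoters those PIRs contact;
* :func:`di_enrichment` — are genes connected to candidate-variant-bearing
  PIRs more likely to be differentially interacting than genes connected to
  rest-variant-bearing PIRs? (2x2 Fisher's exact test);
* :func:`gene_set_enrichment` — one-sided Fisher enrichment of a query gene
  set for an annotation (e.g. blood-cell-count trait genes) within a stated
  universe;
* :func:`interval_enrichment` — fold enrichment of one interval set for
  another, with a bedtools-fisher-style 2x2 table whose d cell derives from
  the genome length and the mean merged-interval size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io_formats import GenomicInterval, PipelineConfig, VariantRecord
from .network_di import PIR, PROMOTER, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """A 2x2 contingency test with the derived summary statistics."""

    table: np.ndarray  # 2x2 ints
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]
    odds_ratio: float
    p_value: float | None
    method: str
    fold_enrichment: float | None = None
    extra: dict = field(default_factory=dict)
    computable: bool = True

    def as_dict(self) -> dict:
        def jsonable(v):
            # keep the report strict JSON: inf/nan become strings
            if isinstance(v, float) and not np.isfinite(v):
                return str(v)
            return v

        return {
            "table": self.table.tolist(),
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "odds_ratio": jsonable(self.odds_ratio),
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
            "method": self.method,
            "computable": self.computable,
            **{k: jsonable(v) for k, v in self.extra.items()},
        }


def _odds_ratio(table: np.ndarray) -> float:
    a, b = table[0]
    c, d = table[1]
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def _fisher(table: np.ndarray, alternative: str) -> float:
    return float(fisher_exact(table, alternative=alternative)[1])


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return multipletests(list(pvalues), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# variant -> PIR -> gene links
# ---------------------------------------------------------------------------


def overlap_variants_pirs(
    variants: Iterable[VariantRecord],
    network: nx.Graph,
) -> dict[str, list[tuple[str, tuple[str, ...]]]]:
    """Map each variant to the merged PIR nodes containing its position.

    A variant lies in a PIR iff its position is inside ``[start, end)`` of
    the merged node interval. Each hit carries the genes whose promoters are
    adjacent to that PIR in the network. Variants outside all PIRs map to an
    empty list.
    """
    trees: dict[str, IntervalTree] = {}
    for node, data in network.nodes(data=True):
        if data.get("kind") != PIR:
            continue
        trees.setdefault(data["chrom"], IntervalTree()).addi(
            data["start"], data["end"], node
        )
    links: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for variant in variants:
        hits = []
        tree = trees.get(variant.interval.chrom)
        if tree is not None:
            for hit in sorted(tree[variant.pos]):
                pir_node = hit.data
                genes = tuple(
                    sorted(
                        network.nodes[nbr].get("gene")
                        or nbr.removeprefix("gene:")
                        for nbr in network.neighbors(pir_node)
                        if network.nodes[nbr].get("kind") == PROMOTER
                    )
                )
                hits.append((pir_node, genes))
        links[variant.vid] = hits
    return links


def variant_gene_links(
    links: Mapping[str, list[tuple[str, tuple[str, ...]]]],
) -> dict[str, set[str]]:
    """Flatten PIR-resolved links to variant -> set of genes."""
    return {
        vid: {g for _pir, genes in hits for g in genes} for vid, hits in links.items()
    }


# ---------------------------------------------------------------------------
# DI enrichment (candidate- vs rest-connected genes)
# ---------------------------------------------------------------------------


def di_enrichment(
    links: Mapping[str, set[str]],
    candidate_variants: set[str],
    di_calls: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> EnrichmentResult:
    """Candidate-connected vs rest-connected DI-gene enrichment.

    Genes linked to at least one candidate variant form the candidate-
    connected group; genes linked only to non-candidate variants form the
    rest-connected group (a gene linked to both counts as candidate-
    connected). Genes with no variant-bearing PIR are excluded. The 2x2
    table {candidate, rest} x {DI, not DI} is tested with Fisher's exact
    test (sidedness from ``config.fisher_sided``). With
    ``config.pair_level_enrichment`` the unit of analysis is the
    (gene, variant) pair instead of the gene.
    """
    config = config or PipelineConfig()
    di_status = dict(zip(di_calls["gene"], di_calls["is_di"]))

    if config.pair_level_enrichment:
        cand_pairs, rest_pairs = set(), set()
        for vid, genes in links.items():
            bucket = cand_pairs if vid in candidate_variants else rest_pairs
            for g in genes:
                if g in di_status:
                    bucket.add((g, vid))
        cand_units = cand_pairs
        rest_units = rest_pairs - cand_pairs
        is_di = lambda unit: bool(di_status[unit[0]])  # noqa: E731
        unit_name = "pairs"
    else:
        cand_genes, rest_genes = set(), set()
        for vid, genes in links.items():
            bucket = cand_genes if vid in candidate_variants else rest_genes
            bucket.update(g for g in genes if g in di_status)
        cand_units = cand_genes
        rest_units = rest_genes - cand_genes  # dominance: candidate wins
        is_di = lambda unit: bool(di_status[unit])  # noqa: E731
        unit_name = "genes"

    a = sum(1 for u in cand_units if is_di(u))
    b = len(cand_units) - a
    c = sum(1 for u in rest_units if is_di(u))
    d = len(rest_units) - c
    table = np.array([[a, b], [c, d]], dtype=int)
    extra = {
        "unit": unit_name,
        "n_candidate": len(cand_units),
        "n_rest": len(rest_units),
        "di_fraction_candidate": a / len(cand_units) if cand_units else float("nan"),
        "di_fraction_rest": c / len(rest_units) if rest_units else float("nan"),
    }
    if not cand_units or not rest_units:
        return EnrichmentResult(
            table,
            ("candidate-connected", "rest-connected"),
            ("DI", "not DI"),
            float("nan"),
            None,
            "fisher_exact/not-computable",
            extra=extra,
            computable=False,
        )
    p = _fisher(table, config.fisher_sided)
    return EnrichmentResult(
        table,
        ("candidate-connected", "rest-connected"),
        ("DI", "not DI"),
        _odds_ratio(table),
        p,
        f"fisher_exact/{config.fisher_sided}",
        extra=extra,
    )


# ---------------------------------------------------------------------------
# gene-set (trait) enrichment
# ---------------------------------------------------------------------------


def gene_set_enrichment(
    query: set[str],
    trait: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """One-sided Fisher enrichment of ``query`` for ``trait`` in ``universe``.

    ``fold_enrichment = (overlap/|query|) / (|trait ∩ universe|/|universe|)``.
    """
    if not universe or not query:
        raise ParameterError("query and universe must be non-empty")
    if not query <= universe:
        raise ParameterError("query genes must be a subset of the universe")
    trait_u = trait & universe
    a = len(query & trait_u)
    b = len(query) - a
    c = len(trait_u) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=int)
    p = _fisher(table, "greater")
    if trait_u:
        fold = (a / len(query)) / (len(trait_u) / len(universe))
    else:
        fold = 0.0
    return EnrichmentResult(
        table,
        ("query", "not query"),
        ("trait", "not trait"),
        _odds_ratio(table),
        p,
        "fisher_exact/greater",
        fold_enrichment=fold,
        extra={"n_query": len(query), "n_trait": len(trait_u), "n_universe": len(universe)},
    )


# ---------------------------------------------------------------------------
# interval (enhancer-mark) enrichment
# ---------------------------------------------------------------------------


def _covered_bp(intervals: Sequence[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def _count_overlapping(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> int:
    trees: dict[str, IntervalTree] = {}
    for iv in targets:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    n = 0
    for iv in queries:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            n += 1
    return n


def interval_enrichment(
    query: Sequence[GenomicInterval],
    annotation: Sequence[GenomicInterval],
    genome_length: int,
    config: PipelineConfig | None = None,
) -> EnrichmentResult:
    """Fold enrichment of a query interval set for an annotation set.

    Both sets are merged (overlapping intervals unioned) first. The 2x2
    table follows the bedtools-fisher construction: a = merged query
    intervals overlapping the annotation, b = those not, c = merged
    annotation intervals not hit by any query, and d fills the rest of a
    genome partitioned into slots of the mean merged-interval length. That d
    cell is an acknowledged approximation, so the coverage-based fold
    enrichment ``(a/(a+b)) / (annotation bp / genome bp)`` is the headline
    statistic and the p-value is secondary.
    """
    config = config or PipelineConfig()
    q = merge_intervals(query) if query else []
    ann = merge_intervals(annotation) if annotation else []
    union_cov = _covered_bp(merge_intervals(list(query) + list(annotation))) if (
        query or annotation
    ) else 0
    if genome_length < union_cov:
        raise ParameterError(
            f"genome_length {genome_length} smaller than covered bp {union_cov}"
        )
    a = _count_overlapping(q, ann)
    b = len(q) - a
    c = len(ann) - _count_overlapping(ann, q)
    lengths = [iv.length for iv in q + ann]
    mean_len = float(np.mean(lengths)) if lengths else float(genome_length)
    d = max(0, int(genome_length / mean_len) - a - b - c)
    table = np.array([[a, b], [c, d]], dtype=int)
    ann_cov = _covered_bp(ann)
    if q and ann_cov > 0:
        fold = (a / len(q)) / (ann_cov / genome_length)
    else:
        fold = 0.0
    p = _fisher(table, config.fisher_sided)
    return EnrichmentResult(
        table,
        ("query overlap", "query no-overlap"),
        ("annotation", "background"),
        _odds_ratio(table),
        p,
        f"fisher_exact/{config.fisher_sided} (bedtools-fisher-style table)",
        fold_enrichment=fold,
        extra={
            "annotation_covered_bp": ann_cov,
            "genome_length": genome_length,
            "n_query_merged": len(q),
            "n_annotation_merged": len(ann),
        },
    )
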