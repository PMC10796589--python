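"""Interactome networks and per-gene rewiring statistics (JI / OCE).

For each cell line and treatment condition a simple undirected graph is
built with promoters, promoter-interacting regions (PIRs) and variant
probes as nodes. An edge connects an anchor to a distal region when some
replicate carries a significant call (supporting pairs >= 4,
Bonferroni-adjusted p < 0.001 by default).

Connectivity change of a node x between two networks A and B is measured by

    JI_x  = |N_A(x) ∩ N_B(x)| / |N_A(x) ∪ N_B(x)|      (Jaccard index)
    OCE_x = |N_A(x) ∩ N_B(x)| / min(|N_A(x)|, |N_B(x)|) (overlap coefficient)

where N_X(x) is the neighbor set of x in network X. OCE equals 1 whenever
the smaller neighborhood is contained in the larger, so it is the stricter
change measure: a gene that only loses connections keeps OCE = 1.

A promoter is *differentially interacting* (DI) when OCE < 1, 0 < JI <= 0.5
and its mean TPM across the two compared conditions exceeds 0.2. JI = 0
cases are excluded to avoid calling genes that merely gain or lose their
entire (often single-edge) neighborhood.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParameterError
from .io_formats import (
    CONDITIONS,
    ExpressionTable,
    GenomicInterval,
    InteractionCall,
    PipelineConfig,
)

logger = logging.getLogger(__name__)

PROMOTER = "promoter"
PIR = "pir"
PROBE = "variant_probe"
CONTROL = "control"

SIMILARITY_COLUMNS = ("node", "kind", "gene", "deg_a", "deg_b", "n_common", "ji", "oce")
DI_COLUMNS = ("gene", "deg_a", "deg_b", "ji", "oce", "mean_tpm", "is_di", "reason")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union all mutually overlapping intervals (strict overlap, per chromosome)."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        current = ivs[0]
        for iv in ivs[1:]:
            if iv.start < current.end:  # strict overlap; touching stays separate
                current = current.union(iv)
            else:
                merged.append(current)
                current = iv
        merged.append(current)
    return merged


class _PirIndex:
    """Maps a distal interval to its merged PIR node id."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.merged = merge_intervals(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.merged:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in self._by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs])

    def lookup(self, iv: GenomicInterval) -> GenomicInterval:
        ivs = self._by_chrom.get(iv.chrom)
        if ivs is None:
            raise ConsistencyError(f"interval {iv} outside the merged PIR namespace")
        idx = int(np.searchsorted(self._starts[iv.chrom], iv.start, side="right")) - 1
        for j in (idx, idx + 1):
            if 0 <= j < len(ivs) and ivs[j].overlaps(iv):
                return ivs[j]
        raise ConsistencyError(f"interval {iv} outside the merged PIR namespace")


def _anchor_node(call: InteractionCall) -> tuple[str, str]:
    """(node id, kind) of the anchor end of a call."""
    if call.anchor_kind == "promoter":
        return f"gene:{call.gene or call.anchor_id}", PROMOTER
    if call.anchor_kind == "variant_probe":
        return f"probe:{call.anchor_id}", PROBE
    return f"ctrl:{call.anchor_id}", CONTROL


def _passes(call: InteractionCall, config: PipelineConfig) -> bool:
    return (
        call.supporting_pairs >= config.min_supporting_pairs
        and call.adj_p < config.adj_p_network
    )


def build_network(
    calls: Sequence[InteractionCall],
    cell_line: str,
    condition: str,
    config: PipelineConfig | None = None,
    pir_index: _PirIndex | None = None,
    replicates: Sequence[int] | None = None,
) -> nx.Graph:
    """Build one interactome network for a cell line and condition.

    An edge exists iff at least one replicate of the condition carries a
    call with enough supporting pairs and adjusted p below the network
    threshold. Distal regions that overlap are merged into single PIR nodes
    (union interval) so the same enhancer is one node across anchors; pass a
    shared ``pir_index`` (from :func:`build_network_pair`) when networks will
    be compared, so node identities match across conditions.

    ``replicates`` restricts to a subset of replicates (per-replicate mode).
    """
    config = config or PipelineConfig()
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    kept = [
        c
        for c in calls
        if c.cell_line == cell_line
        and c.condition == condition
        and (replicates is None or c.replicate in replicates)
        and _passes(c, config)
    ]
    if pir_index is None:
        pir_index = _PirIndex([c.distal for c in kept]) if kept else _PirIndex([])

    g = nx.Graph(cell_line=cell_line, condition=condition)
    for call in kept:
        anchor, kind = _anchor_node(call)
        merged = pir_index.lookup(call.distal)
        pir_node = f"pir:{merged}"
        g.add_node(anchor, kind=kind, gene=call.gene)
        g.add_node(
            pir_node,
            kind=PIR,
            chrom=merged.chrom,
            start=merged.start,
            end=merged.end,
        )
        g.add_edge(anchor, pir_node)
    return g


def build_network_pair(
    calls: Sequence[InteractionCall],
    cell_line: str,
    condition_a: str,
    condition_b: str,
    config: PipelineConfig | None = None,
) -> tuple[nx.Graph, nx.Graph]:
    """Build the two condition networks over a shared merged-PIR namespace.

    Merging runs over the union of all passing calls of the cell line in
    either condition, so a distal fragment shifted by a few base pairs is
    the same node in both networks and JI is not deflated by coordinate
    jitter.
    """
    config = config or PipelineConfig()
    union = [
        c.distal
        for c in calls
        if c.cell_line == cell_line
        and c.condition in (condition_a, condition_b)
        and _passes(c, config)
    ]
    index = _PirIndex(union) if union else _PirIndex([])
    net_a = build_network(calls, cell_line, condition_a, config, pir_index=index)
    net_b = build_network(calls, cell_line, condition_b, config, pir_index=index)
    return net_a, net_b


def _check_pir_namespaces(net_a: nx.Graph, net_b: nx.Graph) -> None:
    """Raise if distinct PIR node ids from the two networks overlap."""
    ivs: dict[str, GenomicInterval] = {}
    for g in (net_a, net_b):
        for n, data in g.nodes(data=True):
            if data.get("kind") == PIR:
                ivs[n] = GenomicInterval(data["chrom"], data["start"], data["end"])
    by_chrom: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for node, iv in ivs.items():
        by_chrom.setdefault(iv.chrom, []).append((iv, node))
    for chrom, pairs in by_chrom.items():
        pairs.sort(key=lambda p: (p[0].start, p[0].end))
        for (iv1, n1), (iv2, n2) in zip(pairs, pairs[1:]):
            if n1 != n2 and iv1.overlaps(iv2):
                raise ConsistencyError(
                    f"PIR nodes {n1} and {n2} overlap: the networks were not "
                    "built over a shared merged-PIR namespace"
                )


def node_similarity(
    net_a: nx.Graph,
    net_b: nx.Graph,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-node JI and OCE between two networks.

    One row per node present (with at least one neighbor) in either network,
    with columns :data:`SIMILARITY_COLUMNS`. ``oce`` is NaN (undefined) when
    the node is absent from one network (min degree 0). With
    ``config.pir_neighbors_only`` a promoter's neighbor set is restricted to
    PIR nodes.
    """
    config = config or PipelineConfig()
    _check_pir_namespaces(net_a, net_b)

    def neighbors(g: nx.Graph, node: str) -> frozenset:
        if node not in g:
            return frozenset()
        nbrs = g.neighbors(node)
        if config.pir_neighbors_only and g.nodes[node].get("kind") == PROMOTER:
            nbrs = (n for n in nbrs if g.nodes[n].get("kind") == PIR)
        return frozenset(nbrs)

    rows = []
    for node in sorted(set(net_a.nodes) | set(net_b.nodes)):
        na, nb = neighbors(net_a, node), neighbors(net_b, node)
        if not na and not nb:
            continue
        common = len(na & nb)
        ji = common / len(na | nb)
        min_deg = min(len(na), len(nb))
        oce = common / min_deg if min_deg > 0 else np.nan
        data = (net_a if node in net_a else net_b).nodes[node]
        rows.append(
            (
                node,
                data.get("kind", ""),
                data.get("gene", ""),
                len(na),
                len(nb),
                common,
                ji,
                oce,
            )
        )
    return pd.DataFrame(rows, columns=list(SIMILARITY_COLUMNS))


def node_similarity_per_replicate(
    calls: Sequence[InteractionCall],
    cell_line: str,
    condition_a: str,
    condition_b: str,
    config: PipelineConfig | None = None,
    replicates: Sequence[int] = (1, 2),
) -> pd.DataFrame:
    """Replicate-resolved JI/OCE: one network per replicate and condition,
    similarity averaged over all replicate pairings (A rep i vs B rep j).

    Alternative mode to the default union-per-condition networks; NaN OCE
    values are ignored in the average (all-NaN stays NaN).
    """
    config = config or PipelineConfig()
    union = [
        c.distal
        for c in calls
        if c.cell_line == cell_line
        and c.condition in (condition_a, condition_b)
        and _passes(c, config)
    ]
    index = _PirIndex(union) if union else _PirIndex([])
    frames = []
    for ra, rb in itertools.product(replicates, repeat=2):
        net_a = build_network(calls, cell_line, condition_a, config, index, [ra])
        net_b = build_network(calls, cell_line, condition_b, config, index, [rb])
        frames.append(node_similarity(net_a, net_b, config))
    combined = pd.concat(frames, ignore_index=True)
    agg = combined.groupby(["node", "kind", "gene"], as_index=False).agg(
        deg_a=("deg_a", "mean"),
        deg_b=("deg_b", "mean"),
        n_common=("n_common", "mean"),
        ji=("ji", "mean"),
        oce=("oce", "mean"),
    )
    return agg


def call_di_genes(
    similarities: pd.DataFrame,
    expression: ExpressionTable,
    cell_line: str,
    conditions: tuple[str, str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Apply the DI rule to promoter nodes.

    is_di <=> OCE < 1 AND 0 < JI <= ji_max AND mean_tpm > tpm_min, where
    mean_tpm averages the gene's TPM over the samples of the two compared
    conditions. Non-promoter nodes are dropped; genes failing a criterion
    are reported with ``is_di = False`` and a reason code (``ji_zero``,
    ``ji_above_max``, ``oce_one``, ``oce_undefined``, ``not_expressed``).
    """
    config = config or PipelineConfig()
    promoters = similarities[similarities["kind"] == PROMOTER]
    rows = []
    for row in promoters.itertuples(index=False):
        gene = row.gene or row.node.removeprefix("gene:")
        mean_tpm = expression.mean_tpm(gene, cell_line, conditions)
        reasons = []
        if np.isnan(row.oce):
            reasons.append("oce_undefined")
        elif row.oce >= 1:
            reasons.append("oce_one")
        if row.ji == 0:
            reasons.append("ji_zero")
        elif row.ji > config.ji_max:
            reasons.append("ji_above_max")
        if mean_tpm <= config.tpm_min:
            reasons.append("not_expressed")
        is_di = not reasons
        rows.append(
            (
                gene,
                row.deg_a,
                row.deg_b,
                row.ji,
                row.oce,
                mean_tpm,
                is_di,
                "di" if is_di else ";".join(reasons),
            )
        )
    return pd.DataFrame(rows, columns=list(DI_COLUMNS))
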