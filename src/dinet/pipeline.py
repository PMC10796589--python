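"""End-to-end orchestration of the analysis stages.

Glue used by the CLI, the test suite and the acceptance script: build the
two condition networks, compute per-gene similarities and DI calls, run the
cohort stage, link variants to genes through PIRs and test the candidate-
vs-rest DI enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .cohort import (
    CohortAssignment,
    cluster_patients,
    cohort_allele_stats,
    filter_candidates,
)
from .integrate_enrich import (
    EnrichmentResult,
    di_enrichment,
    overlap_variants_pirs,
    variant_gene_links,
)
from .io_formats import (
    ExpressionTable,
    GenotypeMatrix,
    InteractionCall,
    PipelineConfig,
)
from .network_di import (
    build_network_pair,
    call_di_genes,
    node_similarity,
    node_similarity_per_replicate,
)
from .synthetic_data import (
    SimulatedCohort,
    SyntheticTruth,
    evaluate_recovery,
    simulate_expression,
    simulate_genotypes,
    simulate_interactions,
)


@dataclass
class InteractomeComparison:
    net_a: nx.Graph
    net_b: nx.Graph
    similarities: pd.DataFrame
    di_calls: pd.DataFrame

    @property
    def union_network(self) -> nx.Graph:
        return nx.compose(self.net_a, self.net_b)

    @property
    def di_genes(self) -> set[str]:
        return set(self.di_calls.loc[self.di_calls["is_di"], "gene"])


def compare_interactomes(
    calls: Sequence[InteractionCall],
    expression: ExpressionTable,
    cell_line: str,
    condition_a: str,
    condition_b: str,
    config: PipelineConfig | None = None,
) -> InteractomeComparison:
    """Networks, JI/OCE and DI calls for one cell line and condition pair."""
    config = config or PipelineConfig()
    net_a, net_b = build_network_pair(calls, cell_line, condition_a, condition_b, config)
    if config.per_replicate:
        sims = node_similarity_per_replicate(
            calls, cell_line, condition_a, condition_b, config
        )
    else:
        sims = node_similarity(net_a, net_b, config)
    di = call_di_genes(sims, expression, cell_line, (condition_a, condition_b), config)
    return InteractomeComparison(net_a, net_b, sims, di)


def run_cohort_stage(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeMatrix,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> tuple[CohortAssignment, pd.DataFrame]:
    """Cluster patients and compute candidate-flagged allele statistics."""
    config = config or PipelineConfig()
    assignment = cluster_patients(phenotypes, config, seed=seed)
    stats = filter_candidates(cohort_allele_stats(genotypes, assignment), config)
    return assignment, stats


@dataclass
class SyntheticRunResult:
    comparison: InteractomeComparison
    cohort: SimulatedCohort
    assignment: CohortAssignment
    stats: pd.DataFrame
    links: dict[str, set[str]]
    enrichment: EnrichmentResult
    recovery: dict[str, float]

    @property
    def candidate_variants(self) -> set[str]:
        return set(self.stats.loc[self.stats["is_candidate"], "variant"])


def run_synthetic_end_to_end(
    truth: SyntheticTruth,
    config: PipelineConfig | None = None,
) -> SyntheticRunResult:
    """Generate a synthetic dataset in memory and run the full pipeline.

    Interactions -> networks -> JI/OCE -> DI calls; phenotypes/genotypes ->
    cohorts -> candidate variants; variant-PIR-gene links -> DI enrichment;
    recovery metrics against the planted truth.
    """
    config = config or PipelineConfig()
    calls = simulate_interactions(truth, config)
    expression = simulate_expression(truth, config)
    comparison = compare_interactomes(
        calls,
        expression,
        truth.cell_line,
        truth.condition_a,
        truth.condition_b,
        config,
    )
    cohort = simulate_genotypes(truth, config)
    assignment, stats = run_cohort_stage(
        cohort.phenotypes, cohort.genotypes, config, seed=truth.seed
    )
    candidate_ids = set(stats.loc[stats["is_candidate"], "variant"])
    pir_links = overlap_variants_pirs(cohort.genotypes.variants, comparison.union_network)
    links = variant_gene_links(pir_links)
    enrichment = di_enrichment(links, candidate_ids, comparison.di_calls, config)
    recovery = evaluate_recovery(truth, comparison.di_genes, candidate_ids)
    return SyntheticRunResult(
        comparison, cohort, assignment, stats, links, enrichment, recovery
    )
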