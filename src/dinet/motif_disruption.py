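"""Allele effects on predicted TF binding affinity.

A sequence window of motif length is scored against a position probability
matrix with an information-content-weighted sum: position i contributes its
base probability weighted by w_i = IC_i / sum(IC), where IC_i is the
information content (2 - Shannon entropy, log2, with a small pseudocount) of
column i. The raw score is min-max normalized over all possible sequences,
giving a *relative score* in [0, 1] — 1 for the consensus, 0 for the
per-position minimum-probability sequence. Positions that matter for binding
therefore dominate the score, and substitutions at uninformative positions
barely move it.

The *effect size* (ES) of a variant against a motif is
``score_alt - score_ref`` at the best window/strand covering the variant
(the one maximizing the better allele's score, capturing both gain and loss
of binding); |ES| >= ``strong_es_min`` classifies the disruption as strong.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ScoringError
from .io_formats import (
    BASE_INDEX,
    BASES,
    ExpressionTable,
    PWM,
    PipelineConfig,
    VariantRecord,
    fetch_sequence,
)

logger = logging.getLogger(__name__)

_IC_PSEUDOCOUNT = 1e-3
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DISRUPTION_COLUMNS = (
    "variant",
    "motif_id",
    "tf_name",
    "strand",
    "window_start",
    "score_ref",
    "score_alt",
    "effect_size",
    "classification",
)

TRIPLET_COLUMNS = (
    "variant",
    "gene",
    "tf_name",
    "motif_id",
    "effect_size",
    "classification",
    "gene_tpm",
    "tf_tpm",
)


@dataclass(frozen=True)
class MotifDisruption:
    """Best-window ref/alt relative scores of one variant against one PWM."""

    variant: str
    motif_id: str
    tf_name: str
    strand: str
    window_start: int
    score_ref: float
    score_alt: float
    effect_size: float
    classification: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=256)
def _pwm_profile(pwm: PWM) -> tuple[np.ndarray, float, float]:
    """(per-position IC weights x probabilities matrix, min raw, max raw)."""
    p = pwm.array
    padj = (p + _IC_PSEUDOCOUNT) / (1 + 4 * _IC_PSEUDOCOUNT)
    ic = 2.0 + (padj * np.log2(padj)).sum(axis=1)
    total = ic.sum()
    w = ic / total if total > 0 else np.full(len(ic), 1.0 / len(ic))
    weighted = w[:, None] * p
    return weighted, float(weighted.min(axis=1).sum()), float(weighted.max(axis=1).sum())


def pwm_relative_score(pwm: PWM, sequence: str) -> float:
    """Relative (min-max normalized, IC-weighted) score of one window.

    Returns 1.0 by convention for a fully uninformative PWM (max == min,
    e.g. all-uniform columns). Ambiguous bases raise :class:`ScoringError`.
    """
    sequence = sequence.upper()
    if len(sequence) != pwm.length:
        raise ScoringError(
            f"window length {len(sequence)} != motif length {pwm.length}"
        )
    try:
        idx = [BASE_INDEX[b] for b in sequence]
    except KeyError as exc:
        raise ScoringError(f"ambiguous base {exc} in window {sequence!r}") from exc
    weighted, lo, hi = _pwm_profile(pwm)
    raw = float(weighted[np.arange(pwm.length), idx].sum())
    if hi - lo <= 1e-12:
        return 1.0
    return (raw - lo) / (hi - lo)


def _classify(effect_size: float, config: PipelineConfig) -> str:
    if abs(effect_size) < 1e-12:
        return "neutral"
    return "strong" if abs(effect_size) >= config.strong_es_min else "weak"


def disruption_effect(
    pwm: PWM,
    genome: Mapping[str, str],
    variant: VariantRecord,
    config: PipelineConfig | None = None,
) -> MotifDisruption | None:
    """Score one variant against one PWM over all covering windows/strands.

    The window and strand maximizing ``max(score_ref, score_alt)`` is
    selected (ties: leftmost window, then + strand); both alleles' relative
    scores are reported there. Returns ``None`` (logged) when no valid
    window exists, e.g. the variant is closer than motif length to a contig
    edge. A genome base that does not match the declared ref allele is
    logged and the declared ref is substituted.
    """
    config = config or PipelineConfig()
    L = pwm.length
    pos = variant.pos
    chrom = variant.interval.chrom
    contig_len = len(genome[chrom])

    genome_base = fetch_sequence(genome, chrom, pos, pos + 1)
    if genome_base != variant.ref:
        logger.warning(
            "variant %s: genome base %s != declared ref %s; using declared ref",
            variant.vid,
            genome_base,
            variant.ref,
        )

    best: tuple[float, MotifDisruption] | None = None
    for w_start in range(max(0, pos - L + 1), min(pos, contig_len - L) + 1):
        window = fetch_sequence(genome, chrom, w_start, w_start + L)
        offset = pos - w_start
        ref_window = window[:offset] + variant.ref + window[offset + 1 :]
        alt_window = window[:offset] + variant.alt + window[offset + 1 :]
        for strand in "+-":
            try:
                if strand == "+":
                    s_ref = pwm_relative_score(pwm, ref_window)
                    s_alt = pwm_relative_score(pwm, alt_window)
                else:
                    s_ref = pwm_relative_score(pwm, reverse_complement(ref_window))
                    s_alt = pwm_relative_score(pwm, reverse_complement(alt_window))
            except ScoringError as exc:
                logger.warning("variant %s window %d%s skipped: %s",
                               variant.vid, w_start, strand, exc)
                continue
            key = max(s_ref, s_alt)
            if best is None or key > best[0] + 1e-12:
                es = s_alt - s_ref
                best = (
                    key,
                    MotifDisruption(
                        variant=variant.vid,
                        motif_id=pwm.motif_id,
                        tf_name=pwm.tf_name,
                        strand=strand,
                        window_start=w_start,
                        score_ref=s_ref,
                        score_alt=s_alt,
                        effect_size=es,
                        classification=_classify(es, config),
                    ),
                )
    if best is None:
        logger.warning("variant %s: no valid window for motif %s",
                       variant.vid, pwm.motif_id)
        return None
    return best[1]


def scan_variants(
    pwms: Iterable[PWM],
    genome: Mapping[str, str],
    variants: Iterable[VariantRecord],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Best-window disruption of every variant against every PWM
    (:data:`DISRUPTION_COLUMNS`, one row per variant x motif with a valid
    window)."""
    config = config or PipelineConfig()
    rows = []
    pwms = list(pwms)
    for variant in variants:
        for pwm in pwms:
            d = disruption_effect(pwm, genome, variant, config)
            if d is not None:
                rows.append(
                    (
                        d.variant,
                        d.motif_id,
                        d.tf_name,
                        d.strand,
                        d.window_start,
                        d.score_ref,
                        d.score_alt,
                        d.effect_size,
                        d.classification,
                    )
                )
    return pd.DataFrame(rows, columns=list(DISRUPTION_COLUMNS))


def filter_candidate_triplets(
    disruptions: pd.DataFrame,
    variant_genes: Mapping[str, Iterable[str]],
    expression: ExpressionTable,
    candidate_variants: set[str],
    cell_line: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Final (variant, gene, TF) candidate table.

    A triplet is kept when: the variant passed the cohort candidate filter,
    it lies in a PIR linked to the gene (``variant_genes``), the motif
    disruption is strong, and both the gene and the TF's own gene have mean
    TPM above ``tpm_min`` across all conditions of the cell line. TF names
    absent from the expression table drop the triplet with a logged warning.
    """
    config = config or PipelineConfig()
    rows = []
    strong = disruptions[disruptions["classification"] == "strong"]
    tpm_cache: dict[str, float] = {}

    def tpm_of(gene: str) -> float:
        if gene not in tpm_cache:
            tpm_cache[gene] = expression.mean_tpm(gene, cell_line)
        return tpm_cache[gene]

    for row in strong.itertuples(index=False):
        if row.variant not in candidate_variants:
            continue
        if row.tf_name not in expression.tpm.index:
            logger.warning(
                "TF %s absent from expression table; triplet dropped", row.tf_name
            )
            continue
        tf_tpm = tpm_of(row.tf_name)
        if tf_tpm <= config.tpm_min:
            continue
        for gene in sorted(variant_genes.get(row.variant, ())):
            gene_tpm = tpm_of(gene)
            if gene_tpm <= config.tpm_min:
                continue
            rows.append(
                (
                    row.variant,
                    gene,
                    row.tf_name,
                    row.motif_id,
                    row.effect_size,
                    row.classification,
                    gene_tpm,
                    tf_tpm,
                )
            )
    return pd.DataFrame(rows, columns=list(TRIPLET_COLUMNS))
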