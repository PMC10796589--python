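"""Seeded synthetic dataset with planted ground truth.

The generator emulates the structure of a promoter-capture interactome
study of drug-induced rewiring: two conditions x two replicates of
interaction calls over a toy genome, a patient cohort with divergent allele
frequencies at planted candidate variants, expression tables, a PWM set
whose consensus sites are disrupted by the planted alternate alleles, and
enhancer-mark intervals overlapping a configurable fraction of PIRs.

Planted structure:

* ~10% of genes are differentially interacting (DI): their treated-condition
  neighbor set replaces a ``rewire_fraction`` of the baseline PIRs (at least
  one shared PIR is kept unless ``rewire_fraction == 1``, so the DI rule's
  JI > 0 requirement can fire);
* ~20% of variants are candidates with divergent cohort allele frequencies
  (default 0.05 in low-toxicity vs 0.35 in high-toxicity patients); each
  candidate sits inside a baseline PIR of a DI gene (the enrichment the
  pipeline must detect) and inside a planted PWM consensus site whose
  alternate allele is the lowest-probability base at that position;
* interaction distances are log-normal, calibrated so the mean absolute
  promoter-PIR distance is ~156 kb; PIR length is ~860 bp;
* every true edge is emitted per replicate with ``replicate_detect_prob``;
  Poisson noise edges appear in single replicates.

Each stage draws from its own RNG stream derived from the master seed, so
stages can be regenerated independently and identical seeds give
byte-identical dataset files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError
from .io_formats import (
    BASES,
    ExpressionTable,
    GenomicInterval,
    GenotypeMatrix,
    InteractionCall,
    PWM,
    PipelineConfig,
    VariantRecord,
    write_bed,
    write_expression,
    write_fasta,
    write_genotypes,
    write_interactions,
    write_phenotypes,
    write_pwms,
)

logger = logging.getLogger(__name__)

# RNG stream ids (spawn keys off the master seed)
_LAYOUT, _INTERACTIONS, _GENOTYPES, _SEQUENCES, _EXPRESSION = range(5)

MEAN_INTERACTION_DISTANCE = 156_000  # bp, calibration target for edge distances
PIR_LENGTH = 860  # bp, the capture design's single-enhancer resolution
_DISTANCE_SIGMA = 1.0  # log-normal shape; mu solved from the mean


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class PlantedGene:
    gene: str
    tss: int
    baseline_pirs: tuple[GenomicInterval, ...]
    treated_pirs: tuple[GenomicInterval, ...]
    is_di: bool


@dataclass(frozen=True)
class PlantedVariant:
    vid: str
    pos: int  # 0-based
    ref: str
    alt: str
    host_pir: GenomicInterval
    is_candidate: bool
    af_lt: float
    af_ht: float
    motif_id: str | None = None  # candidates only
    motif_offset: int | None = None  # variant offset inside the planted window


@dataclass
class SyntheticTruth:
    """Planted parameters ("intent") of one synthetic dataset."""

    seed: int
    chrom: str
    genome_length: int
    cell_line: str
    condition_a: str
    condition_b: str
    cohort_sizes: tuple[int, int]  # (n_HT, n_LT)
    rewire_fraction: float
    replicate_detect_prob: float
    noise_edge_rate: float
    missing_rate: float
    mark_fraction: float
    plant_enrichment: bool
    genes: dict[str, PlantedGene] = field(default_factory=dict)
    variants: dict[str, PlantedVariant] = field(default_factory=dict)
    pwms: list[PWM] = field(default_factory=list)

    @property
    def di_genes(self) -> set[str]:
        return {g for g, pg in self.genes.items() if pg.is_di}

    @property
    def candidate_variants(self) -> set[str]:
        return {v for v, pv in self.variants.items() if pv.is_candidate}

    @property
    def af_pairs(self) -> dict[str, tuple[float, float]]:
        return {v: (pv.af_lt, pv.af_ht) for v, pv in self.variants.items()}

    @property
    def all_pirs(self) -> list[GenomicInterval]:
        seen = set()
        out = []
        for pg in self.genes.values():
            for pir in pg.baseline_pirs + pg.treated_pirs:
                if pir not in seen:
                    seen.add(pir)
                    out.append(pir)
        return out

    def variant_records(self) -> list[VariantRecord]:
        recs = [
            VariantRecord(
                pv.vid, GenomicInterval(self.chrom, pv.pos, pv.pos + 1), pv.ref, pv.alt
            )
            for pv in self.variants.values()
        ]
        return sorted(recs, key=lambda r: r.pos)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genes"] = {
            g: {
                "tss": pg.tss,
                "baseline_pirs": [[p.chrom, p.start, p.end] for p in pg.baseline_pirs],
                "treated_pirs": [[p.chrom, p.start, p.end] for p in pg.treated_pirs],
                "is_di": pg.is_di,
            }
            for g, pg in self.genes.items()
        }
        d["variants"] = {
            v: {
                "pos": pv.pos,
                "ref": pv.ref,
                "alt": pv.alt,
                "host_pir": [pv.host_pir.chrom, pv.host_pir.start, pv.host_pir.end],
                "is_candidate": pv.is_candidate,
                "af_lt": pv.af_lt,
                "af_ht": pv.af_ht,
                "motif_id": pv.motif_id,
                "motif_offset": pv.motif_offset,
            }
            for v, pv in self.variants.items()
        }
        d["pwms"] = [
            {"motif_id": p.motif_id, "tf_name": p.tf_name, "matrix": p.array.tolist()}
            for p in self.pwms
        ]
        d["cohort_sizes"] = list(self.cohort_sizes)
        return d


@dataclass
class SimulatedCohort:
    """Genotypes, phenotypes and the generating cohort labels."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    true_labels: dict[str, str]  # patient -> HT/LT


def _informative_pwms(rng: np.random.Generator, n_motifs: int, length: int) -> list[PWM]:
    """Motifs whose information content concentrates at one core position.

    The core column is sharply peaked (0.94/0.03/0.02/0.01) and flanks are
    weakly informative (0.4/0.3/0.2/0.1 shuffled), so a single substitution
    at the core ablates most of the IC-weighted binding signal — the planted
    variants are by construction strong-effect. A uniform control motif
    (zero information everywhere) is appended last.
    """
    core_probs = np.array([0.94, 0.03, 0.02, 0.01])
    flank_probs = np.array([0.4, 0.3, 0.2, 0.1])
    pwms = []
    for i in range(n_motifs):
        core_pos = int(rng.integers(2, length - 2))
        mat = np.empty((length, 4))
        for j in range(length):
            probs = core_probs if j == core_pos else flank_probs
            mat[j] = probs[rng.permutation(4)]
        pwms.append(PWM.from_array(f"SYN{i:03d}", f"TF{i}", mat))
    uniform = np.full((length, 4), 0.25)
    pwms.append(PWM.from_array("SYNU00", "TFU", uniform))
    return pwms


def _core_position(pwm: PWM) -> int:
    """Position of maximum information content (the planted core column)."""
    p = pwm.array
    padj = (p + 1e-3) / (1 + 4e-3)
    ic = 2.0 + (padj * np.log2(padj)).sum(axis=1)
    return int(np.argmax(ic))


def _sample_pir(
    rng: np.random.Generator, tss: int, genome_length: int
) -> GenomicInterval:
    mu = np.log(MEAN_INTERACTION_DISTANCE) - _DISTANCE_SIGMA**2 / 2
    dist = rng.lognormal(mu, _DISTANCE_SIGMA)
    sign = 1 if rng.random() < 0.5 else -1
    length = int(np.clip(rng.normal(PIR_LENGTH, 100), 300, 2000))
    start = int(np.clip(tss + sign * dist, 0, genome_length - length - 1))
    return GenomicInterval("chr1", start, start + length)


def simulate_truth(
    config: PipelineConfig | None = None,
    n_genes: int = 200,
    n_variants: int = 100,
    *,
    seed: int | None = None,
    di_fraction: float = 0.1,
    candidate_fraction: float = 0.2,
    rewire_fraction: float = 0.6,
    replicate_detect_prob: float = 0.95,
    noise_edge_rate: float = 0.1,
    candidate_af_pair: tuple[float, float] = (0.05, 0.35),
    rest_af_range: tuple[float, float] = (0.25, 0.5),
    cohort_sizes: tuple[int, int] = (54, 42),
    mean_degree: float = 4.0,
    genome_length: int = 10_000_000,
    n_motifs: int = 8,
    motif_length: int = 10,
    missing_rate: float = 0.02,
    mark_fraction: float = 0.7,
    plant_enrichment: bool = True,
    cell_line: str = "CMK",
    condition_a: str = "none",
    condition_b: str = "carboplatin",
) -> SyntheticTruth:
    """Plant the full ground truth: gene layout, rewiring, variants, PWMs.

    Deterministic given the seed (``config.rng_seed`` unless ``seed`` is
    passed). ~``di_fraction`` of genes are DI and ~``candidate_fraction`` of
    variants are candidates; cohort sizes default to (54, 42).
    """
    config = config or PipelineConfig()
    seed = config.rng_seed if seed is None else seed
    if n_genes < 20:
        raise ParameterError("n_genes must be >= 20")
    if n_variants < 10:
        raise ParameterError("n_variants must be >= 10")
    if not (0 < rewire_fraction <= 1):
        raise ParameterError("rewire_fraction must be in (0, 1]")
    if not (0 < replicate_detect_prob <= 1):
        raise ParameterError("replicate_detect_prob must be in (0, 1]")
    if noise_edge_rate < 0:
        raise ParameterError("noise_edge_rate must be >= 0")
    for af in (*candidate_af_pair, *rest_af_range):
        if not (0 <= af <= 1):
            raise ParameterError(f"allele frequency {af} outside [0, 1]")

    rng = _rng(seed, _LAYOUT)
    truth = SyntheticTruth(
        seed=seed,
        chrom="chr1",
        genome_length=genome_length,
        cell_line=cell_line,
        condition_a=condition_a,
        condition_b=condition_b,
        cohort_sizes=cohort_sizes,
        rewire_fraction=rewire_fraction,
        replicate_detect_prob=replicate_detect_prob,
        noise_edge_rate=noise_edge_rate,
        missing_rate=missing_rate,
        mark_fraction=mark_fraction,
        plant_enrichment=plant_enrichment,
    )

    truth.pwms = _informative_pwms(rng, n_motifs, motif_length)
    informative = truth.pwms[:-1]  # last is the uniform control

    # --- genes, degrees, rewiring -------------------------------------
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    n_di = max(1, round(di_fraction * n_genes))
    di_set = set(rng.choice(n_genes, size=n_di, replace=False).tolist())
    tss = np.sort(rng.integers(5_000, genome_length - 5_000, size=n_genes))
    for i, gene in enumerate(gene_names):
        is_di = i in di_set
        degree = max(2 if is_di else 1, int(rng.poisson(mean_degree)))
        baseline = tuple(
            _sample_pir(rng, int(tss[i]), genome_length) for _ in range(degree)
        )
        if is_di:
            k = max(1, round(rewire_fraction * degree))
            if rewire_fraction < 1:
                k = min(k, degree - 1)  # keep >= 1 shared PIR so JI > 0
            treated = baseline[: degree - k] + tuple(
                _sample_pir(rng, int(tss[i]), genome_length) for _ in range(k)
            )
        else:
            treated = baseline
        truth.genes[gene] = PlantedGene(gene, int(tss[i]), baseline, treated, is_di)

    # --- variants ------------------------------------------------------
    n_cand = max(1, round(candidate_fraction * n_variants))
    di_pirs = []
    seen = set()
    for gene in gene_names:
        pg = truth.genes[gene]
        if pg.is_di:
            for pir in pg.baseline_pirs:
                if pir not in seen:
                    seen.add(pir)
                    di_pirs.append(pir)
    all_pirs = truth.all_pirs
    min_len = 2 * motif_length + 2
    usable = [p for p in all_pirs if p.length >= min_len]
    usable_di = [p for p in di_pirs if p.length >= min_len]
    if len(usable) < n_variants:
        raise PlacementError("not enough PIRs to host one variant each")
    cand_pool = usable_di if plant_enrichment else usable
    if len(cand_pool) < n_cand:
        raise PlacementError("not enough DI-gene PIRs to host candidate variants")

    cand_hosts = [cand_pool[j] for j in rng.choice(len(cand_pool), n_cand, replace=False)]
    remaining = [p for p in usable if p not in set(cand_hosts)]
    rest_hosts = [
        remaining[j] for j in rng.choice(len(remaining), n_variants - n_cand, replace=False)
    ]

    taken_pos: set[int] = set()
    for i in range(n_variants):
        is_cand = i < n_cand
        host = cand_hosts[i] if is_cand else rest_hosts[i - n_cand]
        if host.length < min_len:
            raise PlacementError(f"PIR {host} too short to host a motif")
        pos = int(rng.integers(host.start + motif_length, host.end - motif_length))
        while pos in taken_pos:  # variants must occupy distinct positions
            pos = int(rng.integers(host.start + motif_length, host.end - motif_length))
        taken_pos.add(pos)
        if is_cand:
            pwm = informative[i % len(informative)]
            offset = _core_position(pwm)
            col = pwm.array[offset]
            ref = BASES[int(col.argmax())]
            alt = BASES[int(col.argmin())]
            af_lt, af_ht = candidate_af_pair
            motif_id, motif_offset = pwm.motif_id, offset
        else:
            ref, alt = [BASES[j] for j in rng.choice(4, size=2, replace=False)]
            af = float(np.round(rng.uniform(*rest_af_range), 3))
            af_lt = af_ht = af
            motif_id = motif_offset = None
        vid = f"v{i:04d}"
        truth.variants[vid] = PlantedVariant(
            vid, pos, ref, alt, host, is_cand, af_lt, af_ht, motif_id, motif_offset
        )
    return truth


def simulate_interactions(
    truth: SyntheticTruth, config: PipelineConfig | None = None
) -> list[InteractionCall]:
    """Emit interaction calls for both conditions x two replicates.

    Every true promoter-PIR edge is emitted per replicate independently
    with ``replicate_detect_prob``; Poisson noise edges (rate
    ``noise_edge_rate`` per gene per condition-replicate) connect random
    promoters to random PIRs and appear in a single replicate. All emitted
    calls pass the network thresholds (supporting pairs and adjusted p).
    """
    config = config or PipelineConfig()
    rng = _rng(truth.seed, _INTERACTIONS)
    all_pirs = truth.all_pirs
    calls: list[InteractionCall] = []

    def emit(gene: str, pir: GenomicInterval, condition: str, replicate: int) -> None:
        calls.append(
            InteractionCall(
                anchor_id=f"p_{gene}",
                anchor_kind="promoter",
                gene=gene,
                distal=pir,
                supporting_pairs=int(config.min_supporting_pairs + rng.poisson(6)),
                adj_p=float(10 ** -rng.uniform(3.5, 8.0)),
                cell_line=truth.cell_line,
                condition=condition,
                replicate=replicate,
            )
        )

    gene_names = sorted(truth.genes)
    for condition in (truth.condition_a, truth.condition_b):
        treated = condition == truth.condition_b
        for replicate in (1, 2):
            for gene in gene_names:
                pg = truth.genes[gene]
                pirs = pg.treated_pirs if treated else pg.baseline_pirs
                for pir in pirs:
                    if rng.random() < truth.replicate_detect_prob:
                        emit(gene, pir, condition, replicate)
            n_noise = rng.poisson(truth.noise_edge_rate * len(gene_names))
            for _ in range(n_noise):
                gene = gene_names[int(rng.integers(len(gene_names)))]
                pg = truth.genes[gene]
                true_set = set(pg.treated_pirs if treated else pg.baseline_pirs)
                pir = all_pirs[int(rng.integers(len(all_pirs)))]
                if pir in true_set:
                    continue  # skip rather than duplicate a true edge
                emit(gene, pir, condition, replicate)
    return calls


def simulate_genotypes(
    truth: SyntheticTruth, config: PipelineConfig | None = None
) -> SimulatedCohort:
    """Draw patient genotypes and blood-count phenotypes.

    Each patient's genotype at a variant is Binomial(2, AF of their cohort);
    candidate variants use the divergent planted pair, rest variants the
    shared AF. Phenotypes are three blood-count values from two
    well-separated Gaussian clusters (high-toxicity patients have the lower
    nadir counts). A small fraction of genotypes is set missing.
    """
    rng = _rng(truth.seed, _GENOTYPES)
    n_ht, n_lt = truth.cohort_sizes
    n = n_ht + n_lt
    patients = [f"P{i:03d}" for i in range(n)]
    cohort = np.array(["HT"] * n_ht + ["LT"] * n_lt)
    rng.shuffle(cohort)
    true_labels = dict(zip(patients, cohort))

    pheno_means = {"HT": 2.0, "LT": 5.0}  # nadir counts, arbitrary clinical units
    pheno = np.empty((n, 3))
    for i, lab in enumerate(cohort):
        pheno[i] = rng.normal(pheno_means[lab], 0.5, size=3)
    phenotypes = pd.DataFrame(
        np.round(pheno, 4),
        index=pd.Index(patients, name="patient"),
        columns=["neutropenia", "leukopenia", "thrombocytopenia"],
    )

    records = truth.variant_records()
    gts = np.empty((len(records), n), dtype=np.int16)
    ht_mask = cohort == "HT"
    for vi, rec in enumerate(records):
        pv = truth.variants[rec.vid]
        af = np.where(ht_mask, pv.af_ht, pv.af_lt)
        gts[vi] = rng.binomial(2, af)
        if truth.missing_rate > 0:
            miss = rng.random(n) < truth.missing_rate
            gts[vi, miss] = GenotypeMatrix.MISSING
    return SimulatedCohort(
        GenotypeMatrix(records, patients, gts), phenotypes, true_labels
    )


def simulate_expression(
    truth: SyntheticTruth, config: PipelineConfig | None = None
) -> ExpressionTable:
    """TPM table for both conditions x two replicates of the cell line.

    Genes draw a log-normal baseline (median ~20 TPM); 5% of non-DI genes
    are silenced (TPM below the expression cutoff) to exercise the filter.
    The synthetic TF genes are always expressed.
    """
    rng = _rng(truth.seed, _EXPRESSION)
    genes = sorted(truth.genes)
    tf_genes = [p.tf_name for p in truth.pwms]
    all_genes = genes + tf_genes
    base = rng.lognormal(np.log(20), 1.0, size=len(all_genes))
    non_di = [g for g in genes if not truth.genes[g].is_di]
    n_silent = max(1, len(non_di) // 20)
    silent_idx = rng.choice(len(non_di), size=n_silent, replace=False)
    silent = {non_di[i] for i in silent_idx}
    for i, g in enumerate(all_genes):
        if g in silent:
            base[i] = rng.uniform(0.0, 0.15)
    samples = [
        f"{truth.cell_line}_{cond}_{rep}"
        for cond in (truth.condition_a, truth.condition_b)
        for rep in (1, 2)
    ]
    noise = rng.lognormal(0.0, 0.1, size=(len(all_genes), len(samples)))
    tpm = pd.DataFrame(
        np.round(base[:, None] * noise, 4),
        index=pd.Index(all_genes, name="gene"),
        columns=samples,
    )
    return ExpressionTable(tpm)


def simulate_sequences(
    truth: SyntheticTruth, config: PipelineConfig | None = None
) -> tuple[dict[str, str], list[PWM], list[GenomicInterval]]:
    """Toy genome, PWM set and enhancer-mark intervals.

    Each candidate variant sits inside a planted consensus site of its PWM
    (plus strand): the reference allele matches the consensus and the
    alternate allele is the position's lowest-probability base. Enhancer
    marks overlap ``mark_fraction`` of the PIRs plus background intervals.
    """
    rng = _rng(truth.seed, _SEQUENCES)
    base_idx = rng.integers(0, 4, size=truth.genome_length).astype(np.uint8)
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    seq = base_arr[base_idx]

    pwm_by_id = {p.motif_id: p for p in truth.pwms}
    # plant all consensus windows first, then the ref bases, so a ref base of
    # one variant cannot be clobbered by a later variant's window
    for pv in truth.variants.values():
        if pv.is_candidate:
            pwm = pwm_by_id[pv.motif_id]
            consensus = pwm.consensus
            w_start = pv.pos - pv.motif_offset
            seq[w_start : w_start + pwm.length] = np.frombuffer(
                consensus.encode(), dtype=np.uint8
            )
    for pv in truth.variants.values():
        seq[pv.pos] = ord(pv.ref)
    genome = {truth.chrom: seq.tobytes().decode()}

    marks: list[GenomicInterval] = []
    for pir in truth.all_pirs:
        if rng.random() < truth.mark_fraction:
            start = max(0, pir.start - int(rng.integers(0, 200)))
            end = min(truth.genome_length, pir.end + int(rng.integers(0, 200)))
            marks.append(GenomicInterval(truth.chrom, start, end))
    for _ in range(20):  # background marks away from any planted structure
        start = int(rng.integers(0, truth.genome_length - 500))
        marks.append(GenomicInterval(truth.chrom, start, start + 500))
    marks.sort()
    return genome, list(truth.pwms), marks


def write_dataset(
    truth: SyntheticTruth,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Materialize the full dataset under ``outdir``; returns the manifest.

    Files: interactions.tsv, genotypes.vcf, expression.tsv, phenotypes.tsv,
    genome.fa, motifs.jaspar, marks.bed, truth.json, manifest.json.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    calls = simulate_interactions(truth, config)
    cohort = simulate_genotypes(truth, config)
    expression = simulate_expression(truth, config)
    genome, pwms, marks = simulate_sequences(truth, config)

    write_interactions(calls, outdir / "interactions.tsv")
    write_genotypes(
        cohort.genotypes,
        outdir / "genotypes.vcf",
        contigs={truth.chrom: truth.genome_length},
    )
    write_expression(expression, outdir / "expression.tsv")
    write_phenotypes(cohort.phenotypes, outdir / "phenotypes.tsv")
    write_fasta(genome, outdir / "genome.fa")
    write_pwms(pwms, outdir / "motifs.jaspar")
    write_bed(marks, outdir / "marks.bed")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)

    manifest = {}
    for name in (
        "interactions.tsv",
        "genotypes.vcf",
        "expression.tsv",
        "phenotypes.tsv",
        "genome.fa",
        "motifs.jaspar",
        "marks.bed",
        "truth.json",
    ):
        path = outdir / name
        data = path.read_bytes()
        manifest[name] = {
            "bytes": len(data),
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def evaluate_recovery(
    truth: SyntheticTruth,
    di_genes_called: set[str],
    candidates_called: set[str],
) -> dict[str, float]:
    """Recovery metrics against the planted truth.

    Precision / recall / F1 for DI genes (positives = planted DI genes) and
    sensitivity / specificity for candidate variants over the full planted
    variant universe.
    """
    true_di = truth.di_genes
    tp = len(di_genes_called & true_di)
    fp = len(di_genes_called - true_di)
    fn = len(true_di - di_genes_called)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )

    true_cand = truth.candidate_variants
    universe = set(truth.variants)
    negatives = universe - true_cand
    tp_v = len(candidates_called & true_cand)
    fp_v = len((candidates_called & universe) - true_cand)
    sensitivity = tp_v / len(true_cand) if true_cand else 0.0
    specificity = (len(negatives) - fp_v) / len(negatives) if negatives else 0.0
    return {
        "di_precision": precision,
        "di_recall": recall,
        "di_f1": f1,
        "candidate_sensitivity": sensitivity,
        "candidate_specificity": specificity,
        "candidate_fpr": 1.0 - specificity,
    }
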