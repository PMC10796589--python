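"""Readers/writers for the external file formats and the run configuration.

All coordinates are stored 0-based half-open (BED convention) in memory.
Interaction tables and the validated-interval coordinates printed in the
literature are 1-based inclusive; conversion happens at this I/O boundary
and nowhere else.

Formats handled here:

* interaction calls — TSV with a fixed, documented header (see
  :data:`INTERACTION_COLUMNS`); 1-based inclusive distal coordinates;
* genotypes — VCF 4.x via :mod:`cyvcf2` (biallelic SNVs retained);
* expression — TSV, genes x samples, sample columns named
  ``<cell_line>_<condition>_<replicate>``;
* phenotypes — TSV, patients x three blood-count variables;
* PWMs — JASPAR text via :mod:`Bio.motifs`, counts normalized per column;
* intervals — BED3+;
* configuration — YAML mirroring :class:`PipelineConfig`.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import motifs as bio_motifs

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

CONDITIONS = ("none", "carboplatin", "gemcitabine")
ANCHOR_KINDS = ("promoter", "variant_probe", "control")

#: canonical column order of the interaction-call TSV dialect.
#: ``distal_start``/``distal_end`` are 1-based inclusive in the file.
INTERACTION_COLUMNS = (
    "anchor_id",
    "anchor_kind",
    "gene",
    "distal_chrom",
    "distal_start",
    "distal_end",
    "supporting_pairs",
    "adj_p",
    "cell_line",
    "condition",
    "replicate",
)

PHENOTYPE_COLUMNS = ("neutropenia", "leukopenia", "thrombocytopenia")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based (``[start, end)``)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @classmethod
    def from_1based(cls, chrom: str, start: int, end: int) -> "GenomicInterval":
        """Build from a 1-based inclusive span as printed in the literature."""
        return cls(chrom, start - 1, end)

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValidationError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def to_1based_str(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __str__(self) -> str:  # 0-based, for node ids
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class InteractionCall:
    """One anchor-to-distal proximity call from a capture Hi-C experiment."""

    anchor_id: str
    anchor_kind: str
    gene: str
    distal: GenomicInterval
    supporting_pairs: int
    adj_p: float
    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.anchor_kind not in ANCHOR_KINDS:
            raise ValidationError(f"unknown anchor_kind {self.anchor_kind!r}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.supporting_pairs < 0:
            raise ValidationError("supporting_pairs must be >= 0")
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValidationError(f"adj_p {self.adj_p} outside [0, 1]")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV: 1-bp interval plus ref/alt alleles."""

    vid: str
    interval: GenomicInterval
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.interval.length != 1:
            raise ValidationError(f"variant {self.vid} interval is not 1 bp")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"variant {self.vid} alleles must be A/C/G/T")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.vid} ref == alt")

    @property
    def pos(self) -> int:
        """0-based position."""
        return self.interval.start


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix: variants x patients, -1 encodes missing."""

    variants: list[VariantRecord]
    patients: list[str]
    genotypes: np.ndarray  # int8/int16, shape (n_variants, n_patients)

    MISSING = -1

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.genotypes.shape != (len(self.variants), len(self.patients)):
            raise ValidationError("genotype matrix shape mismatch")
        valid = np.isin(self.genotypes, (-1, 0, 1, 2))
        if not valid.all():
            raise ValidationError("genotypes must be in {0, 1, 2} or -1 (missing)")

    @property
    def variant_ids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.genotypes, index=self.variant_ids, columns=self.patients
        )


@dataclass
class ExpressionTable:
    """TPM table (genes x samples) plus per-sample metadata.

    Samples are named ``<cell_line>_<condition>_<replicate>``; the metadata
    frame is derived from those names on construction.
    """

    tpm: pd.DataFrame  # index: gene, columns: sample names

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("TPM values must be non-negative")
        meta = []
        for sample in self.tpm.columns:
            parts = str(sample).rsplit("_", 2)
            if len(parts) != 3:
                raise FormatError(
                    f"sample column {sample!r} is not <cell>_<condition>_<rep>"
                )
            cell, condition, rep = parts
            if condition not in CONDITIONS:
                raise FormatError(f"sample {sample!r}: unknown condition {condition!r}")
            meta.append((sample, cell, condition, int(rep)))
        self.samples = pd.DataFrame(
            meta, columns=["sample", "cell_line", "condition", "replicate"]
        ).set_index("sample")

    def mean_tpm(
        self,
        gene: str,
        cell_line: str,
        conditions: Sequence[str] | None = None,
    ) -> float:
        """Mean TPM of ``gene`` over the samples of one cell line.

        ``conditions`` restricts to a subset of treatments; ``None`` averages
        over all treatments of the cell line. A gene absent from the table is
        treated as unexpressed (TPM 0) with a logged warning.
        """
        mask = self.samples["cell_line"] == cell_line
        if conditions is not None:
            mask &= self.samples["condition"].isin(conditions)
        cols = self.samples.index[mask]
        if len(cols) == 0:
            raise ParameterError(
                f"no expression samples for cell line {cell_line!r}"
                + (f" conditions {conditions}" if conditions else "")
            )
        if gene not in self.tpm.index:
            logger.warning("gene %s absent from expression table; TPM treated as 0", gene)
            return 0.0
        return float(self.tpm.loc[gene, cols].mean())


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A/C/G/T (rows are positions)."""

    motif_id: str
    tf_name: str
    matrix: tuple  # tuple of 4-tuples so the dataclass stays hashable

    @classmethod
    def from_array(cls, motif_id: str, tf_name: str, matrix: np.ndarray) -> "PWM":
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValidationError(f"PWM {motif_id}: matrix must be L x 4")
        if (m < 0).any():
            raise ValidationError(f"PWM {motif_id}: negative entries")
        sums = m.sum(axis=1)
        # normalize; zero-count columns fall back to uniform
        zero = sums == 0
        m[zero] = 0.25
        sums[zero] = 1.0
        m = m / sums[:, None]
        return cls(motif_id, tf_name, tuple(tuple(row) for row in m))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def length(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.array.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        rc = self.array[::-1, ::-1]
        return PWM.from_array(self.motif_id, self.tf_name, rc)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline with their default values.

    Defaults mirror the published analysis: interactions need at least four
    supporting read pairs; Bonferroni-adjusted p below 0.01 in general and
    below 0.001 for network generation; DI genes require overlap coefficient
    below 1 and 0 < JI <= 0.5 with mean TPM > 0.2; the cohort
    allele-difference threshold ACEthr is 0.25.
    """

    min_supporting_pairs: int = 4
    adj_p_general: float = 0.01
    adj_p_network: float = 0.001
    ji_max: float = 0.5
    tpm_min: float = 0.2
    ace_thr: float = 0.25
    strong_es_min: float = 0.4
    fisher_sided: str = "two-sided"
    k_clusters: int = 2
    rng_seed: int = 0
    # alternative analysis modes, off by default
    per_replicate: bool = False
    pir_neighbors_only: bool = False
    require_two_carriers: bool = False
    pair_level_enrichment: bool = False

    def __post_init__(self) -> None:
        if self.min_supporting_pairs < 0:
            raise ParameterError("min_supporting_pairs must be >= 0")
        for name in ("adj_p_general", "adj_p_network"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ParameterError(f"{name} must be in (0, 1]")
        if not (0 < self.ji_max <= 1):
            raise ParameterError("ji_max must be in (0, 1]")
        if self.tpm_min < 0:
            raise ParameterError("tpm_min must be >= 0")
        if not (0 < self.ace_thr < 1):
            raise ParameterError("ace_thr must be in (0, 1)")
        if not (0 <= self.strong_es_min <= 1):
            raise ParameterError("strong_es_min must be in [0, 1]")
        if self.fisher_sided not in ("two-sided", "greater", "less"):
            raise ParameterError("fisher_sided must be two-sided/greater/less")
        if self.k_clusters != 2:
            raise ParameterError("only k_clusters = 2 is supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# interaction-call TSV
# ---------------------------------------------------------------------------


def read_interactions(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[InteractionCall]:
    """Read an interaction-call TSV into :class:`InteractionCall` records.

    ``columns`` maps the canonical column names of
    :data:`INTERACTION_COLUMNS` to the names actually used in the file,
    allowing other dialects. Distal coordinates are 1-based inclusive in the
    file and converted to 0-based half-open here.
    """
    rename = dict(columns or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    actual = {canon: rename.get(canon, canon) for canon in INTERACTION_COLUMNS}
    missing = [a for a in actual.values() if a not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")

    calls: list[InteractionCall] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rec = {canon: getattr(row, actual[canon]) for canon in INTERACTION_COLUMNS}
        try:
            start1 = int(rec["distal_start"])
            end1 = int(rec["distal_end"])
            if start1 < 1 or end1 < start1:
                raise ValueError(f"span {start1}-{end1} is not a 1-based inclusive span")
            distal = GenomicInterval.from_1based(str(rec["distal_chrom"]), start1, end1)
            calls.append(
                InteractionCall(
                    anchor_id=str(rec["anchor_id"]),
                    anchor_kind=str(rec["anchor_kind"]),
                    gene="" if pd.isna(rec["gene"]) else str(rec["gene"]),
                    distal=distal,
                    supporting_pairs=int(rec["supporting_pairs"]),
                    adj_p=float(rec["adj_p"]),
                    cell_line=str(rec["cell_line"]),
                    condition=str(rec["condition"]),
                    replicate=int(rec["replicate"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
    return calls


def write_interactions(calls: Iterable[InteractionCall], path: str | Path) -> None:
    """Write calls in the documented TSV dialect (1-based inclusive spans)."""
    rows = [
        (
            c.anchor_id,
            c.anchor_kind,
            c.gene,
            c.distal.chrom,
            c.distal.start + 1,
            c.distal.end,
            c.supporting_pairs,
            f"{c.adj_p:.6g}",
            c.cell_line,
            c.condition,
            c.replicate,
        )
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=list(INTERACTION_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a :class:`GenotypeMatrix`.

    Genotype is the number of alt alleles; ``./.`` becomes missing (-1).
    Multi-allelic and non-SNV records are skipped with a logged count.
    """
    from cyvcf2 import VCF  # deferred: import is slow

    vcf = VCF(str(path))
    patients = list(vcf.samples)
    if not patients:
        raise FormatError(f"{path}: VCF has no sample columns")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if ref not in BASES or alt not in BASES:
            skipped += 1
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{ref}:{alt}"
        interval = GenomicInterval(v.CHROM, v.POS - 1, v.POS)
        dosage = np.empty(len(patients), dtype=np.int16)
        for j, gt in enumerate(v.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                dosage[j] = GenotypeMatrix.MISSING
            else:
                dosage[j] = sum(1 for a in alleles if a == 1)
        variants.append(VariantRecord(vid, interval, ref, alt))
        rows.append(dosage)
    if skipped:
        logger.info("%s: skipped %d multi-allelic/non-SNV records", path, skipped)
    gts = np.vstack(rows) if rows else np.empty((0, len(patients)), dtype=np.int16)
    return GenotypeMatrix(variants, patients, gts)


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", GenotypeMatrix.MISSING: "./."}


def write_genotypes(
    gm: GenotypeMatrix,
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.patients)
            + "\n"
        )
        for var, row in zip(gm.variants, gm.genotypes):
            gts = "\t".join(_GT_STRING[int(g)] for g in row)
            fh.write(
                f"{var.interval.chrom}\t{var.pos + 1}\t{var.vid}\t{var.ref}\t"
                f"{var.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# expression / phenotypes
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.tpm.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the patient blood-count table (patients x 3 numeric phenotypes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing phenotype column(s): {missing}")
    return df[list(PHENOTYPE_COLUMNS)].astype(float)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# PWMs (JASPAR)
# ---------------------------------------------------------------------------


def read_pwms(path: str | Path) -> list[PWM]:
    """Read JASPAR-format matrices; counts are column-normalized to
    probabilities and all-zero columns fall back to uniform 0.25."""
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # biopython raises bare Exception subclasses
            raise FormatError(f"{path}: cannot parse JASPAR file: {exc}") from exc
        pwms = []
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in BASES], dtype=float).T
            pwms.append(PWM.from_array(m.matrix_id or m.name, m.name, counts))
    return pwms


def write_pwms(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write PWMs in JASPAR text format (probabilities, full precision)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_name}\n")
            arr = pwm.array
            for i, base in enumerate(BASES):
                vals = " ".join(f"{v:.10f}" for v in arr[:, i])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# BED intervals / FASTA
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path} line {line_no}: fewer than 3 BED columns")
            try:
                intervals.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path} line {line_no}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch an uppercase subsequence from a dict-of-strings or pyfaidx.Fasta."""
    seq = genome[chrom][start:end]
    return str(seq).upper()
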