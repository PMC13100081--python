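"""Readers and writers for every external format the engine touches.

Coordinate conventions, stated once and asserted in tests:

* VCF positions are 1-based.
* BED intervals are 0-based half-open; ``Interval`` stores them that way and
  converts to 1-based inclusive on demand.
* Protein and CDS positions in effect annotations are 1-based.

Depth tables may be sparse; absent positions count as depth 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CONSEQUENCE_CLASSES = frozenset(
    {"missense", "synonymous", "stop_gain", "inframe_indel", "frameshift", "other"}
)
FRAME_STATUSES = frozenset({"in_frame", "out_of_frame", "unknown"})
CONFIDENCE_LEVELS = frozenset({"low", "medium", "high"})

_NUCLEOTIDES = frozenset("ACGT")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectAnnotation:
    """Functional annotation of one variant on one transcript.

    Which position fields are populated depends on ``consequence_class``:
    missense carries protein fields, indels/frameshifts carry CDS fields.
    """

    gene_symbol: str = ""
    transcript_id: str = ""
    consequence_class: str = "other"
    protein_position: int | None = None
    ref_aa: str = ""
    alt_aa: str = ""
    cds_position: int | None = None
    cds_ref: str = ""
    cds_alt: str = ""

    def __post_init__(self) -> None:
        if self.consequence_class not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence_class {self.consequence_class!r}")


@dataclass(frozen=True)
class SomaticVariant:
    """One filtered tumor-normal variant (one ALT allele) with annotation."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    filter_status: frozenset[str]
    tumor_depth: int
    vaf: float
    effect: EffectAnnotation = field(default_factory=EffectAnnotation)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - _NUCLEOTIDES:
                raise ValueError(f"allele must be non-empty over ACGT: {allele!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.tumor_depth < 0:
            raise ValueError(f"tumor_depth must be >= 0: {self.tumor_depth}")

    @property
    def is_pass(self) -> bool:
        return self.filter_status == frozenset({"PASS"})

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class FusionRecord:
    """One gene-fusion call in the caller's coordinate space."""

    gene5: str
    gene3: str
    breakpoint5: str = "."
    breakpoint3: str = "."
    junction_reads: int = 0
    discordant_pairs: int = 0
    confidence: str = "low"
    frame_status: str = "unknown"
    junction_cds: str = ""
    junction_offset: int = 0

    def __post_init__(self) -> None:
        if self.junction_reads < 0 or self.discordant_pairs < 0:
            raise ValueError("read support counts must be >= 0")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")
        if self.frame_status not in FRAME_STATUSES:
            raise ValueError(f"unknown frame_status {self.frame_status!r}")
        if not 0 <= self.junction_offset <= len(self.junction_cds):
            raise ValueError(
                f"junction_offset {self.junction_offset} outside junction_cds "
                f"of length {len(self.junction_cds)}"
            )

    @property
    def label(self) -> str:
        return f"{self.gene5}::{self.gene3}"


@dataclass
class AbundanceTable:
    """Transcript-level TPM with a transcript-to-gene mapping."""

    tpm: dict[str, float]
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        for tx, value in self.tpm.items():
            if value < 0:
                raise ValueError(f"negative TPM for {tx}: {value}")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval (BED convention)."""

    contig: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")

    def positions_1based(self) -> range:
        """1-based inclusive positions covered by this interval."""
        return range(self.start + 1, self.end + 1)

    @property
    def length(self) -> int:
        return self.end - self.start


class DepthTrack:
    """Sparse per-base depth: (contig, 1-based position) -> depth, missing = 0."""

    def __init__(self, depths: Mapping[str, Mapping[int, int]] | None = None):
        self._depths: dict[str, dict[int, int]] = {}
        if depths:
            for contig, per_pos in depths.items():
                for pos, depth in per_pos.items():
                    self.set(contig, pos, depth)

    def set(self, contig: str, pos: int, depth: int) -> None:
        if depth < 0 or int(depth) != depth:
            raise ValueError(f"depth must be a non-negative integer: {depth}")
        if pos < 1:
            raise ValueError(f"position must be >= 1: {pos}")
        self._depths.setdefault(contig, {})[int(pos)] = int(depth)

    def get(self, contig: str, pos: int) -> int:
        return self._depths.get(contig, {}).get(pos, 0)

    def contigs(self) -> list[str]:
        return sorted(self._depths)

    def items(self) -> Iterable[tuple[str, int, int]]:
        for contig in sorted(self._depths):
            for pos in sorted(self._depths[contig]):
                yield contig, pos, self._depths[contig][pos]

    def __len__(self) -> int:
        return sum(len(v) for v in self._depths.values())


class ProteomeDb:
    """Reference proteome with a substring-membership index over all sequences."""

    _SEP = "#"

    def __init__(self, sequences: Mapping[str, str]):
        for seq_id, seq in sequences.items():
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise FormatError(f"sequence {seq_id} has non-amino-acid characters {bad}")
        self.sequences = dict(sequences)
        self._blob = self._SEP + self._SEP.join(self.sequences.values()) + self._SEP

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteomeDb":
        return cls(read_fasta(path))

    def contains(self, peptide: str) -> bool:
        """True iff *peptide* occurs verbatim inside any proteome sequence."""
        if self._SEP in peptide:
            raise ValueError("peptide may not contain the separator character")
        return peptide in self._blob

    def __len__(self) -> int:
        return len(self.sequences)


# ---------------------------------------------------------------------------
# HLA alleles
# ---------------------------------------------------------------------------

_HLA_RE = re.compile(r"^(?:HLA-)?([ABC])\*?(\d{2,3}):(\d{2,3})$")


def normalize_hla(raw: str) -> str:
    """Normalize a class I allele to ``HLA-A*24:02`` form.

    >>> normalize_hla("A*24:02")
    'HLA-A*24:02'
    """
    m = _HLA_RE.match(raw.strip())
    if not m:
        raise FormatError(f"unrecognized HLA allele {raw!r}")
    return f"HLA-{m.group(1)}*{m.group(2)}:{m.group(3)}"


def read_hla_list(path: str | Path) -> list[str]:
    """One allele per line, with or without the ``HLA-`` prefix."""
    alleles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            alleles.append(normalize_hla(line))
    return alleles


def write_hla_list(alleles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{a}\n" for a in alleles))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Interval]:
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED line needs >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
        if end <= start:
            raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
        name = fields[3] if len(fields) > 3 else ""
        intervals.append(Interval(fields[0], start, end, name))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\n")


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------


def read_depth_table(path: str | Path) -> DepthTrack:
    """3-column tab-separated (contig, 1-based position, depth), samtools-depth style."""
    track = DepthTrack()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: depth line needs 3 columns")
        try:
            pos, depth = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer position or depth") from exc
        try:
            track.set(fields[0], pos, depth)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_depth_table(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, pos, depth in track.items():
            fh.write(f"{contig}\t{pos}\t{depth}\n")


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------


def read_abundance(path: str | Path) -> AbundanceTable:
    """Kallisto-dialect abundance: ``target_id``/``tpm`` columns, optional ``gene_symbol``.

    Transcripts without a gene mapping are assigned to their own ID (warned).
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"target_id", "tpm"} - set(df.columns)
    if missing:
        raise FormatError(f"abundance table missing columns: {sorted(missing)}")
    tpm: dict[str, float] = {}
    gene_of: dict[str, str] = {}
    for row in df.itertuples(index=False):
        tx = str(row.target_id)
        tpm[tx] = float(row.tpm)
        gene = str(getattr(row, "gene_symbol", "")) if "gene_symbol" in df.columns else ""
        if not gene or gene == "nan":
            log.warning("transcript %s has no gene mapping; using its own ID", tx)
            gene = tx
        gene_of[tx] = gene
    return AbundanceTable(tpm=tpm, gene_of=gene_of)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\tgene_symbol\ttpm\n")
        for tx in sorted(table.tpm):
            fh.write(f"{tx}\t{table.gene_of.get(tx, tx)}\t{table.tpm[tx]:.6g}\n")


def gene_tpm(table: AbundanceTable) -> dict[str, float]:
    """Sum transcript-level TPM to gene level; conserves total TPM."""
    totals: dict[str, float] = {}
    for tx, value in table.tpm.items():
        gene = table.gene_of.get(tx, tx)
        totals[gene] = totals.get(gene, 0.0) + value
    return totals


# ---------------------------------------------------------------------------
# somatic VCF + effect table
# ---------------------------------------------------------------------------

EFFECT_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene_symbol",
    "transcript_id",
    "consequence_class",
    "protein_position",
    "ref_aa",
    "alt_aa",
    "cds_position",
    "cds_ref",
    "cds_alt",
]

_VEP_CONSEQUENCE_MAP = {
    "missense_variant": "missense",
    "synonymous_variant": "synonymous",
    "stop_gained": "stop_gain",
    "frameshift_variant": "frameshift",
    "inframe_insertion": "inframe_indel",
    "inframe_deletion": "inframe_indel",
}


def _load_effect_table(path: str | Path) -> dict[tuple[str, int, str, str], EffectAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(EFFECT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"effect table missing columns: {sorted(missing)}")
    effects = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        effects[key] = EffectAnnotation(
            gene_symbol=row.gene_symbol,
            transcript_id=row.transcript_id,
            consequence_class=row.consequence_class or "other",
            protein_position=int(row.protein_position) if row.protein_position else None,
            ref_aa=row.ref_aa,
            alt_aa=row.alt_aa,
            cds_position=int(row.cds_position) if row.cds_position else None,
            cds_ref=row.cds_ref,
            cds_alt=row.cds_alt,
        )
    return effects


def write_effect_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(EFFECT_TABLE_COLUMNS) + "\n")
        for v in variants:
            e = v.effect
            fields = [
                v.chrom,
                str(v.pos),
                v.ref_allele,
                v.alt_allele,
                e.gene_symbol,
                e.transcript_id,
                e.consequence_class,
                str(e.protein_position) if e.protein_position is not None else "",
                e.ref_aa,
                e.alt_aa,
                str(e.cds_position) if e.cds_position is not None else "",
                e.cds_ref,
                e.cds_alt,
            ]
            fh.write("\t".join(fields) + "\n")


def _parse_csq_effect(
    record, alt: str, csq_key: str, csq_fields: list[str]
) -> EffectAnnotation | None:
    """Minimal VEP-style CSQ extraction: only the subfields we model."""
    entries = record.info.get(csq_key)
    if not entries:
        return None
    if isinstance(entries, str):
        entries = (entries,)
    for entry in entries:
        values = dict(zip(csq_fields, entry.split("|")))
        if values.get("Allele") not in (alt, None) and len(entries) > 1:
            continue
        consequence = "other"
        for term in values.get("Consequence", "").split("&"):
            if term in _VEP_CONSEQUENCE_MAP:
                consequence = _VEP_CONSEQUENCE_MAP[term]
                break
        aa = values.get("Amino_acids", "")
        ref_aa, _, alt_aa = aa.partition("/")
        prot_pos = values.get("Protein_position", "").split("-")[0]
        cds_pos = values.get("CDS_position", "").split("-")[0]
        return EffectAnnotation(
            gene_symbol=values.get("SYMBOL", ""),
            transcript_id=values.get("Feature", ""),
            consequence_class=consequence,
            protein_position=int(prot_pos) if prot_pos.isdigit() else None,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            cds_position=int(cds_pos) if cds_pos.isdigit() else None,
        )
    return None


def _find_tumor_sample(vcf: pysam.VariantFile, tumor_sample: str | None) -> str:
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError("VCF has no sample columns; tumor sample required")
    if tumor_sample is not None:
        if tumor_sample not in samples:
            raise FormatError(f"tumor sample {tumor_sample!r} not in VCF samples {samples}")
        return tumor_sample
    for hrec in vcf.header.records:
        if hrec.key == "tumor_sample" and hrec.value in samples:
            return hrec.value
    if "TUMOR" in samples:
        return "TUMOR"
    if len(samples) == 1:
        return samples[0]
    raise FormatError(
        f"cannot identify tumor sample among {samples}; pass tumor_sample explicitly"
    )


def read_somatic_vcf(
    path: str | Path,
    effect_source: str | Path,
    tumor_sample: str | None = None,
) -> list[SomaticVariant]:
    """Parse a tumor-normal somatic VCF into one variant per ALT allele.

    ``effect_source`` is either a path to a companion tab-separated effect table
    keyed by chrom/pos/ref/alt, or the name of an embedded VEP-style INFO key
    (e.g. ``"CSQ"``). Variants without annotation carry consequence ``other``.
    Records whose VAF/depth cannot be parsed are dropped and counted in the log.
    """
    vcf = pysam.VariantFile(str(path))
    tumor = _find_tumor_sample(vcf, tumor_sample)

    effects: dict | None = None
    csq_key: str | None = None
    csq_fields: list[str] = []
    if Path(effect_source).exists():
        effects = _load_effect_table(effect_source)
    elif str(effect_source) in vcf.header.info:
        csq_key = str(effect_source)
        desc = vcf.header.info[csq_key].description or ""
        _, _, fmt = desc.partition("Format: ")
        csq_fields = fmt.split("|")
    else:
        raise FormatError(
            f"effect_source {effect_source!r} is neither an existing file nor an INFO key"
        )

    variants: list[SomaticVariant] = []
    n_bad = 0
    for record in vcf:
        filters = frozenset(record.filter.keys())
        sample = record.samples[tumor]
        ad = sample.get("AD")
        dp = sample.get("DP")
        af = sample.get("AF")
        for alt_index, alt in enumerate(record.alts or ()):
            try:
                if dp is not None:
                    depth = int(dp)
                elif ad is not None:
                    depth = int(sum(ad))
                else:
                    raise ValueError("no DP or AD format field")
                if af is not None:
                    af_values = af if isinstance(af, tuple) else (af,)
                    vaf = float(af_values[alt_index])
                elif ad is not None and sum(ad) > 0:
                    vaf = float(ad[alt_index + 1]) / float(sum(ad))
                else:
                    raise ValueError("no AF or usable AD format field")
                key = (record.chrom, record.pos, record.ref, alt)
                if effects is not None:
                    effect = effects.get(key, EffectAnnotation())
                else:
                    effect = (
                        _parse_csq_effect(record, alt, csq_key, csq_fields)
                        or EffectAnnotation()
                    )
                variants.append(
                    SomaticVariant(
                        chrom=record.chrom,
                        pos=record.pos,
                        ref_allele=record.ref,
                        alt_allele=alt,
                        filter_status=filters,
                        tumor_depth=depth,
                        vaf=round(vaf, 6),
                        effect=effect,
                    )
                )
            except (ValueError, TypeError, IndexError) as exc:
                n_bad += 1
                log.warning(
                    "skipping %s:%s %s>%s: %s", record.chrom, record.pos, record.ref, alt, exc
                )
    if n_bad:
        log.warning("dropped %d record(s) with unparseable VAF/depth", n_bad)
    return variants


def write_somatic_vcf(
    variants: Iterable[SomaticVariant],
    path: str | Path,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
    contigs: Iterable[str] | None = None,
) -> None:
    """Write a minimal tumor-normal VCF (AD/DP/AF format fields, filters declared)."""
    variants = list(variants)
    if contigs is None:
        contigs = sorted({v.chrom for v in variants})
    filter_labels = sorted(
        {label for v in variants for label in v.filter_status if label != "PASS"}
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=neorank\n")
        fh.write(f"##tumor_sample={tumor_sample}\n")
        fh.write(f"##normal_sample={normal_sample}\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        for label in filter_labels:
            fh.write(f'##FILTER=<ID={label},Description="{label}">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tumor_sample}\t{normal_sample}\n"
        )
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref_allele, v.alt_allele)):
            filt = ";".join(sorted(v.filter_status)) or "."
            alt_reads = int(round(v.vaf * v.tumor_depth))
            ref_reads = max(v.tumor_depth - alt_reads, 0)
            tumor_fmt = f"{ref_reads},{alt_reads}:{v.tumor_depth}:{v.vaf:g}"
            normal_fmt = f"{v.tumor_depth},0:{v.tumor_depth}:0"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\t{filt}\t.\t"
                f"AD:DP:AF\t{tumor_fmt}\t{normal_fmt}\n"
            )


# ---------------------------------------------------------------------------
# fusion tables (Arriba dialect)
# ---------------------------------------------------------------------------

_FUSION_MANDATORY = [
    "gene1",
    "gene2",
    "split_reads1",
    "split_reads2",
    "discordant_mates",
    "confidence",
    "reading_frame",
]

_FRAME_MAP = {
    "in-frame": "in_frame",
    "in_frame": "in_frame",
    "out-of-frame": "out_of_frame",
    "out_of_frame": "out_of_frame",
    "stop-codon": "out_of_frame",
    ".": "unknown",
    "": "unknown",
}


def _junction_from_transcript(value: str) -> tuple[str, int]:
    """Arriba marks breakpoints with ``|`` inside the fusion transcript sequence."""
    parts = value.strip().upper().split("|")
    if len(parts) < 2:
        return "", 0
    five = parts[0]
    rest = "".join(parts[1:])
    seq = five + rest
    if set(seq) - _NUCLEOTIDES:
        return "", 0
    return seq, len(five)


def read_fusion_table(
    path: str | Path, junction_fasta: str | Path | None = None
) -> list[FusionRecord]:
    """Parse an Arriba-style fusion TSV.

    ``junction_reads`` is the sum of both split-read columns. The chimeric
    junction sequence comes from a ``fusion_transcript`` column (breakpoint
    marked with ``|``) or, for callers that omit sequence, from a sidecar FASTA
    whose records are named ``gene5::gene3`` with ``offset=N`` in the header.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in _FUSION_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"fusion table missing mandatory columns: {missing}")

    sidecar: dict[str, tuple[str, int]] = {}
    if junction_fasta is not None:
        for rec in SeqIO.parse(str(junction_fasta), "fasta"):
            m = re.search(r"offset=(\d+)", rec.description)
            sidecar[rec.id] = (str(rec.seq).upper(), int(m.group(1)) if m else 0)

    records = []
    for row in df.itertuples(index=False):
        row_d = row._asdict()
        frame_raw = row_d["reading_frame"].strip().lower()
        if frame_raw not in _FRAME_MAP:
            raise FormatError(f"unrecognized reading_frame {frame_raw!r}")
        junction_cds, offset = "", 0
        if "fusion_transcript" in row_d:
            junction_cds, offset = _junction_from_transcript(row_d["fusion_transcript"])
        if not junction_cds:
            label = f"{row_d['gene1']}::{row_d['gene2']}"
            if label in sidecar:
                junction_cds, offset = sidecar[label]
        records.append(
            FusionRecord(
                gene5=row_d["gene1"],
                gene3=row_d["gene2"],
                breakpoint5=row_d.get("breakpoint1", "."),
                breakpoint3=row_d.get("breakpoint2", "."),
                junction_reads=int(row_d["split_reads1"]) + int(row_d["split_reads2"]),
                discordant_pairs=int(row_d["discordant_mates"]),
                confidence=row_d["confidence"].strip().lower(),
                frame_status=_FRAME_MAP[frame_raw],
                junction_cds=junction_cds,
                junction_offset=offset,
            )
        )
    return records


def write_fusion_table(records: Iterable[FusionRecord], path: str | Path) -> None:
    """Write records back out in the Arriba dialect read by :func:`read_fusion_table`."""
    frame_out = {"in_frame": "in-frame", "out_of_frame": "out-of-frame", "unknown": "."}
    with open(path, "w") as fh:
        fh.write(
            "#gene1\tgene2\tbreakpoint1\tbreakpoint2\tsplit_reads1\tsplit_reads2\t"
            "discordant_mates\tconfidence\treading_frame\tfusion_transcript\n"
        )
        for r in records:
            if r.junction_cds:
                transcript = (
                    r.junction_cds[: r.junction_offset] + "|" + r.junction_cds[r.junction_offset :]
                )
            else:
                transcript = "."
            fh.write(
                f"{r.gene5}\t{r.gene3}\t{r.breakpoint5}\t{r.breakpoint3}\t"
                f"{r.junction_reads}\t0\t{r.discordant_pairs}\t{r.confidence}\t"
                f"{frame_out[r.frame_status]}\t{transcript}\n"
            )


# ---------------------------------------------------------------------------
# candidates table
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "sample",
    "source_type",
    "gene_label",
    "peptide",
    "length",
    "hla_allele",
    "rank_percent",
    "rank_percent_wt",
    "agretopicity_index",
    "expression_value",
    "expression_unit",
    "clonality",
    "logistic_weight",
    "expression_component",
    "foreignness",
    "self_match",
    "binder_class",
    "priority_score",
]


def _render(value) -> str:
    if value is None or value == "":
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_candidates_table(rows: Iterable[Mapping], path: str | Path) -> None:
    """Write scored candidates with a fixed column order and fixed float precision.

    Row order is the caller's (already ranked); output is byte-deterministic
    for identical input.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_render(row.get(col)) for col in CANDIDATE_COLUMNS) + "\n")
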