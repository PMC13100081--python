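"""Mutant protein reconstruction and 8-11-mer candidate peptide enumeration.

Covers four event classes: missense SNVs, in-frame indels, frameshifts, and
fusion junctions. The enumeration contract is a sliding window: every 8-11-mer
window that covers at least one altered residue (or straddles a deletion joint
or fusion breakpoint), truncated only by the sequence termini. Peptides
containing a stop or an ambiguous residue are suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import FusionRecord, SomaticVariant

log = logging.getLogger(__name__)

DEFAULT_LENGTHS: tuple[int, ...] = (8, 9, 10, 11)
DEFAULT_MIN_DEPTH = 10

EPITOPE_CONSEQUENCES = frozenset({"missense", "inframe_indel", "frameshift"})

# Standard genetic code; '*' marks stop codons.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


class AnnotationMismatchError(ValueError):
    """Annotation and sequence resources are out of sync."""


@dataclass(frozen=True)
class MutantProteinContext:
    """Reconstructed mutant protein plus the residue span that differs.

    ``altered_span`` is 1-based inclusive on ``mutant_sequence``. When
    ``requires_straddle`` is set (deletion joints), windows must contain both
    span endpoints rather than merely overlap the span.
    """

    mutant_sequence: str
    altered_span: tuple[int, int]
    source_type: str
    gene_label: str
    variant_key: str
    wildtype_sequence: str | None = None
    requires_straddle: bool = False

    def __post_init__(self) -> None:
        a, b = self.altered_span
        if not (1 <= a <= b <= len(self.mutant_sequence)):
            raise ValueError(
                f"altered_span {self.altered_span} outside mutant sequence "
                f"of length {len(self.mutant_sequence)}"
            )
        if self.source_type == "snv" and b != a:
            raise ValueError("missense span must be a single residue")


@dataclass(frozen=True)
class PeptideCandidate:
    sequence: str
    source_type: str
    gene_label: str
    variant_key: str
    window_start: int  # 1-based start in the mutant sequence
    contains_positions: tuple[int, ...]
    wildtype_counterpart: str | None = None

    def __post_init__(self) -> None:
        if not 8 <= len(self.sequence) <= 11:
            raise ValueError(f"peptide length {len(self.sequence)} outside 8..11")
        if "*" in self.sequence or "X" in self.sequence:
            raise ValueError("peptide contains stop or ambiguous residue")


def translate_cds(cds: str) -> str:
    """Translate with the standard code.

    Stops at (and excludes) the first stop codon; a trailing partial codon is
    ignored; any codon with an ambiguous base yields ``X``.
    """
    cds = cds.upper()
    protein = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        aa = GENETIC_CODE.get(codon, "X")
        if aa == "*":
            break
        protein.append(aa)
    return "".join(protein)


def select_epitope_variants(
    variants: Sequence[SomaticVariant], min_depth: int = DEFAULT_MIN_DEPTH
) -> list[SomaticVariant]:
    """Variants eligible for peptide generation.

    PASS, depth-qualified, and of a peptide-producing consequence class.
    Stop-gain is deliberately excluded here (premature termination codons do
    not yield the modeled mutant context and are NMD-prone) although it counts
    toward TMB.
    """
    return [
        v
        for v in variants
        if v.is_pass
        and v.tumor_depth >= min_depth
        and v.effect.consequence_class in EPITOPE_CONSEQUENCES
    ]


def _variant_key(v: SomaticVariant) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref_allele}>{v.alt_allele}"


def build_missense_context(
    v: SomaticVariant, proteins: Mapping[str, str]
) -> MutantProteinContext:
    """Single-residue substitution on the annotated transcript's protein."""
    e = v.effect
    if e.consequence_class != "missense":
        raise ValueError(f"not a missense variant: {e.consequence_class}")
    if e.transcript_id not in proteins:
        raise AnnotationMismatchError(f"no protein sequence for {e.transcript_id}")
    protein = proteins[e.transcript_id]
    pos = e.protein_position
    if pos is None or not 1 <= pos <= len(protein):
        raise AnnotationMismatchError(
            f"protein_position {pos} outside {e.transcript_id} (len {len(protein)})"
        )
    if protein[pos - 1] != e.ref_aa:
        raise AnnotationMismatchError(
            f"{e.transcript_id} position {pos}: annotation says {e.ref_aa}, "
            f"sequence has {protein[pos - 1]}"
        )
    mutant = protein[: pos - 1] + e.alt_aa + protein[pos:]
    return MutantProteinContext(
        mutant_sequence=mutant,
        altered_span=(pos, pos),
        source_type="snv",
        gene_label=e.gene_symbol,
        variant_key=_variant_key(v),
        wildtype_sequence=protein,
    )


def _apply_cds_edit(cds: str, v: SomaticVariant) -> str:
    e = v.effect
    pos = e.cds_position
    if pos is None or not e.cds_ref:
        raise AnnotationMismatchError("indel annotation lacks CDS position/alleles")
    if cds[pos - 1 : pos - 1 + len(e.cds_ref)] != e.cds_ref:
        raise AnnotationMismatchError(
            f"CDS mismatch at {pos}: expected {e.cds_ref}, "
            f"found {cds[pos - 1 : pos - 1 + len(e.cds_ref)]}"
        )
    return cds[: pos - 1] + e.cds_alt + cds[pos - 1 + len(e.cds_ref) :]


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def build_frameshift_context(
    v: SomaticVariant, cds_sequences: Mapping[str, str]
) -> MutantProteinContext | None:
    """Apply a frame-disrupting indel and translate the shifted frame.

    The altered span runs from the first residue differing from the reference
    translation through the new terminus (stop excluded). A frameshift whose
    shifted frame stops immediately yields no context (None, logged).
    """
    e = v.effect
    if e.transcript_id not in cds_sequences:
        raise AnnotationMismatchError(f"no CDS sequence for {e.transcript_id}")
    cds = cds_sequences[e.transcript_id]
    mutant_cds = _apply_cds_edit(cds, v)
    if (len(mutant_cds) - len(cds)) % 3 == 0:
        raise ValueError("length-preserving-frame indel routed to frameshift builder")
    wt_protein = translate_cds(cds)
    mut_protein = translate_cds(mutant_cds)
    first_diff = _common_prefix_len(wt_protein, mut_protein)
    if first_diff >= len(mut_protein):
        log.info("frameshift %s produces no novel residue; skipped", _variant_key(v))
        return None
    return MutantProteinContext(
        mutant_sequence=mut_protein,
        altered_span=(first_diff + 1, len(mut_protein)),
        source_type="frameshift",
        gene_label=e.gene_symbol,
        variant_key=_variant_key(v),
    )


def build_inframe_context(
    v: SomaticVariant, cds_sequences: Mapping[str, str]
) -> MutantProteinContext | None:
    """Apply a frame-preserving indel.

    Insertions: the altered span is the novel residue block. Deletions: no
    altered residue exists, so the span marks the two newly adjacent residues
    and windows must straddle that joint.
    """
    e = v.effect
    if e.transcript_id not in cds_sequences:
        raise AnnotationMismatchError(f"no CDS sequence for {e.transcript_id}")
    cds = cds_sequences[e.transcript_id]
    mutant_cds = _apply_cds_edit(cds, v)
    if (len(mutant_cds) - len(cds)) % 3 != 0:
        raise ValueError("frame-disrupting indel routed to in-frame builder")
    wt_protein = translate_cds(cds)
    mut_protein = translate_cds(mutant_cds)
    if not mut_protein:
        log.info("in-frame indel %s leaves no protein; skipped", _variant_key(v))
        return None
    prefix = _common_prefix_len(wt_protein, mut_protein)
    suffix = 0
    while (
        suffix < min(len(wt_protein), len(mut_protein)) - prefix
        and wt_protein[len(wt_protein) - 1 - suffix] == mut_protein[len(mut_protein) - 1 - suffix]
    ):
        suffix += 1
    altered_len = len(mut_protein) - prefix - suffix
    if altered_len > 0:
        span = (prefix + 1, prefix + altered_len)
        straddle = False
    else:
        # pure deletion: windows must span the joint between prefix and prefix+1
        a = max(prefix, 1)
        b = min(prefix + 1, len(mut_protein))
        span = (a, b)
        straddle = b > a
    return MutantProteinContext(
        mutant_sequence=mut_protein,
        altered_span=span,
        source_type="inframe_indel",
        gene_label=e.gene_symbol,
        variant_key=_variant_key(v),
        requires_straddle=straddle,
    )


def build_context(
    v: SomaticVariant,
    proteins: Mapping[str, str],
    cds_sequences: Mapping[str, str],
) -> MutantProteinContext | None:
    """Dispatch a variant to its context builder by consequence class."""
    cls = v.effect.consequence_class
    if cls == "missense":
        return build_missense_context(v, proteins)
    if cls == "frameshift":
        return build_frameshift_context(v, cds_sequences)
    if cls == "inframe_indel":
        return build_inframe_context(v, cds_sequences)
    raise ValueError(f"no peptide context for consequence {cls!r}")


def _window_ok(start0: int, length: int, ctx: MutantProteinContext) -> bool:
    a, b = ctx.altered_span
    end0 = start0 + length - 1  # inclusive, 0-based
    if ctx.requires_straddle:
        return start0 <= a - 1 and end0 >= b - 1
    return start0 <= b - 1 and end0 >= a - 1


def enumerate_peptides(
    ctx: MutantProteinContext, lengths: Sequence[int] = DEFAULT_LENGTHS
) -> list[PeptideCandidate]:
    """All windows of the requested lengths that cover the altered span.

    Windows are truncated only by sequence termini. A wild-type counterpart
    (same coordinates in the wild-type sequence) is attached for missense only.
    Identical sequences arising from different windows of the same variant are
    de-duplicated keeping the first.
    """
    seq = ctx.mutant_sequence
    a, b = ctx.altered_span
    out: list[PeptideCandidate] = []
    seen: set[str] = set()
    for length in sorted(lengths):
        for start0 in range(0, len(seq) - length + 1):
            if not _window_ok(start0, length, ctx):
                continue
            pep = seq[start0 : start0 + length]
            if "*" in pep or "X" in pep:
                continue
            if pep in seen:
                continue
            seen.add(pep)
            covered = tuple(
                p for p in range(start0 + 1, start0 + length + 1) if a <= p <= b
            )
            wt = None
            if ctx.source_type == "snv" and ctx.wildtype_sequence is not None:
                wt_window = ctx.wildtype_sequence[start0 : start0 + length]
                if len(wt_window) == length and "*" not in wt_window and "X" not in wt_window:
                    wt = wt_window
            out.append(
                PeptideCandidate(
                    sequence=pep,
                    source_type=ctx.source_type,
                    gene_label=ctx.gene_label,
                    variant_key=ctx.variant_key,
                    window_start=start0 + 1,
                    contains_positions=covered,
                    wildtype_counterpart=wt,
                )
            )
    return out


def fusion_peptides(
    f: FusionRecord, lengths: Sequence[int] = DEFAULT_LENGTHS
) -> list[PeptideCandidate]:
    """Junction-spanning peptides from a fusion's chimeric coding sequence.

    Translation starts at ``junction_offset mod 3`` so that the breakpoint
    falls on a codon boundary; only windows containing residues from both
    partners are kept. A stop codon upstream of the junction yields nothing.
    """
    if not 0 <= f.junction_offset <= len(f.junction_cds):
        raise ValueError(
            f"junction_offset {f.junction_offset} inconsistent with sequence "
            f"length {len(f.junction_cds)}"
        )
    frame = f.junction_offset % 3
    protein = translate_cds(f.junction_cds[frame:])
    n5 = (f.junction_offset - frame) // 3  # residues wholly from the 5' partner
    if n5 < 1 or len(protein) <= n5:
        return []  # stop before the junction, or no partner residues to span
    ctx = MutantProteinContext(
        mutant_sequence=protein,
        altered_span=(n5, n5 + 1),
        source_type="fusion",
        gene_label=f.label,
        variant_key=f"{f.breakpoint5}|{f.breakpoint3}",
        requires_straddle=True,
    )
    return enumerate_peptides(ctx, lengths)


def peptide_fasta_header(sample: str, p: PeptideCandidate) -> str:
    """Header for the optional peptide FASTA export."""
    return (
        f"{sample}|{p.source_type}|{p.gene_label}|{p.variant_key}"
        f"|{p.window_start}|{len(p.sequence)}"
    )
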