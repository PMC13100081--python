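"""DNA-RNA concordance calls: functional amplification vs capture artifact
vs transcription-only elevation.

Depth ratios are taken against each sample's own background (mean CDS depth)
to absorb library-size differences. All cutoffs are configurable defaults —
the underlying logic is qualitative: a real amplification shows a somatic
locus-depth excess *and* commensurate RNA overexpression, a capture artifact
shows the depth spike in tumor and matched normal alike, and
transcription-only elevation has the RNA signal without genomic gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import DepthTrack, Interval

LABELS = (
    "concordant_amplification",
    "capture_artifact",
    "transcriptional_only",
    "unremarkable",
)


@dataclass(frozen=True)
class ConcordanceThresholds:
    r_dna: float = 3.0  # locus/background depth ratio calling DNA elevation
    r_somatic: float = 2.0  # tumor-over-normal ratio-of-ratios for somatic gain
    t_abs: float = 50.0  # absolute TPM floor for RNA elevation
    f_rel: float = 5.0  # fold over the cohort reference TPM
    epsilon: float = 1e-9


@dataclass(frozen=True)
class LocusEvidence:
    gene: str
    tumor_locus_depth: float
    normal_locus_depth: float
    tumor_background_depth: float
    normal_background_depth: float
    tpm: float
    cohort_tpm_reference: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "tumor_locus_depth",
            "normal_locus_depth",
            "tumor_background_depth",
            "normal_background_depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")


@dataclass(frozen=True)
class ConcordanceCall:
    gene: str
    dna_elevated: bool
    rna_elevated: bool
    shared_with_normal: bool
    label: str
    tumor_ratio: float = 0.0
    normal_ratio: float = 0.0


def locus_mean_depth(depth: DepthTrack, intervals: Sequence[Interval]) -> float:
    """Arithmetic mean per-base depth over the intervals (absent positions = 0)."""
    if not intervals:
        raise ValueError("empty interval list")
    total = 0
    n = 0
    for iv in intervals:
        for pos in iv.positions_1based():
            total += depth.get(iv.contig, pos)
            n += 1
    return total / n


def _label(dna: bool, rna: bool, shared: bool) -> str:
    if dna and rna and not shared:
        return "concordant_amplification"
    if (dna and not rna) or shared:
        return "capture_artifact"
    if not dna and rna:
        return "transcriptional_only"
    return "unremarkable"


def classify_concordance(
    e: LocusEvidence, thresholds: ConcordanceThresholds = ConcordanceThresholds()
) -> ConcordanceCall:
    """Classify one locus from its depth ratios and expression.

    DNA elevation requires both a locus/background ratio at or above ``r_dna``
    in the tumor and a tumor-over-normal ratio-of-ratios at or above
    ``r_somatic``; a spike present in tumor and normal alike is flagged
    shared (capture artifact). RNA elevation requires TPM at or above
    max(t_abs, f_rel * cohort reference).
    """
    t = thresholds
    if e.tumor_background_depth <= 0 or e.normal_background_depth <= 0:
        raise ValueError("background depths must be > 0")
    tumor_ratio = e.tumor_locus_depth / e.tumor_background_depth
    normal_ratio = e.normal_locus_depth / e.normal_background_depth
    somatic_ratio = tumor_ratio / max(normal_ratio, t.epsilon)
    dna_elevated = tumor_ratio >= t.r_dna and somatic_ratio >= t.r_somatic
    shared = tumor_ratio >= t.r_dna and normal_ratio >= t.r_dna
    rna_threshold = max(t.t_abs, t.f_rel * e.cohort_tpm_reference)
    rna_elevated = e.tpm >= rna_threshold
    return ConcordanceCall(
        gene=e.gene,
        dna_elevated=dna_elevated,
        rna_elevated=rna_elevated,
        shared_with_normal=shared,
        label=_label(dna_elevated, rna_elevated, shared),
        tumor_ratio=tumor_ratio,
        normal_ratio=normal_ratio,
    )


CONCORDANCE_COLUMNS = [
    "sample",
    "gene",
    "tumor_locus_depth",
    "normal_locus_depth",
    "tumor_background_depth",
    "normal_background_depth",
    "tumor_ratio",
    "normal_ratio",
    "tpm",
    "cohort_tpm_reference",
    "dna_elevated",
    "rna_elevated",
    "shared_with_normal",
    "label",
]


def write_concordance_table(
    rows: Iterable[tuple[str, LocusEvidence, ConcordanceCall]], path: str | Path
) -> None:
    """Per-gene tab-separated concordance report."""
    with open(path, "w") as fh:
        fh.write("\t".join(CONCORDANCE_COLUMNS) + "\n")
        for sample, e, call in rows:
            fh.write(
                "\t".join(
                    [
                        sample,
                        e.gene,
                        format(e.tumor_locus_depth, ".6g"),
                        format(e.normal_locus_depth, ".6g"),
                        format(e.tumor_background_depth, ".6g"),
                        format(e.normal_background_depth, ".6g"),
                        format(call.tumor_ratio, ".6g"),
                        format(call.normal_ratio, ".6g"),
                        format(e.tpm, ".6g"),
                        format(e.cohort_tpm_reference, ".6g"),
                        str(call.dna_elevated),
                        str(call.rna_elevated),
                        str(call.shared_with_normal),
                        call.label,
                    ]
                )
                + "\n"
            )
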