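"""Callable-territory definition, normalized mutation burden, Ti/Tv and breadth."""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io_formats import DepthTrack, Interval, SomaticVariant

DEFAULT_MIN_DEPTH = 10

_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass
class CallableTerritory:
    """Merged, sorted 1-based inclusive intervals of positions that are both
    inside CDS and at or above the depth threshold."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for contig, ivs in self.intervals.items():
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1 + 1:
                    raise ValueError(f"intervals on {contig} not disjoint/sorted")

    @property
    def total_bases(self) -> int:
        return sum(e - s + 1 for ivs in self.intervals.values() for s, e in ivs)

    @property
    def total_megabases(self) -> float:
        return self.total_bases / 1e6

    def contains(self, contig: str, pos: int) -> bool:
        ivs = self.intervals.get(contig)
        if not ivs:
            return False
        i = bisect_right(ivs, (pos, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= pos <= ivs[i][1]


@dataclass
class TmbReport:
    nonsyn_count: int
    callable_mb: float
    tmb: float
    titv: float | None = None
    breadth_at_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.breadth_at_threshold is not None and not 0 <= self.breadth_at_threshold <= 1:
            raise ValueError("breadth_at_threshold outside [0,1]")


def _runs(positions: Iterable[int]) -> list[tuple[int, int]]:
    """Collapse a sorted position iterable into maximal (start, end) runs."""
    runs: list[tuple[int, int]] = []
    for pos in positions:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    return runs


def compute_callable(
    depth: DepthTrack, cds: Sequence[Interval], min_depth: int = DEFAULT_MIN_DEPTH
) -> CallableTerritory:
    """CDS positions reaching ``min_depth``, merged into a territory.

    Overlapping CDS intervals are deduplicated so each genomic base counts once.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not cds:
        raise ValueError("empty CDS interval list")
    per_contig: dict[str, set[int]] = {}
    for iv in cds:
        keep = per_contig.setdefault(iv.contig, set())
        for pos in iv.positions_1based():
            if depth.get(iv.contig, pos) >= min_depth:
                keep.add(pos)
    intervals = {
        contig: _runs(sorted(posns)) for contig, posns in per_contig.items() if posns
    }
    return CallableTerritory(intervals={k: intervals[k] for k in sorted(intervals)})


def breadth_of_coverage(
    depth: DepthTrack, target: Sequence[Interval], threshold: int
) -> float:
    """Fraction of target bases with depth >= threshold."""
    if not target:
        raise ValueError("empty target interval list")
    seen: dict[str, set[int]] = {}
    for iv in target:
        seen.setdefault(iv.contig, set()).update(iv.positions_1based())
    total = sum(len(s) for s in seen.values())
    covered = sum(
        1
        for contig, posns in seen.items()
        for pos in posns
        if depth.get(contig, pos) >= threshold
    )
    return covered / total


def is_tmb_eligible(
    v: SomaticVariant,
    territory: CallableTerritory,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> bool:
    """Nonsynonymous burden eligibility.

    Stop-gain counts here (it is a nonsynonymous event) even though it is
    excluded from epitope generation; synonymous and unclassified do not.
    """
    return (
        v.is_pass
        and v.tumor_depth >= min_depth
        and territory.contains(v.chrom, v.pos)
        and v.effect.consequence_class in {"missense", "stop_gain", "frameshift", "inframe_indel"}
    )


def compute_tmb(
    variants: Iterable[SomaticVariant],
    territory: CallableTerritory,
    min_depth: int = DEFAULT_MIN_DEPTH,
    capture_regions: Sequence[Interval] | None = None,
    depth: DepthTrack | None = None,
    target: Sequence[Interval] | None = None,
) -> TmbReport:
    """Mutations per callable megabase, with optional Ti/Tv and breadth add-ons."""
    if territory.total_bases <= 0:
        raise ValueError("zero callable territory: sample unusable for TMB")
    variants = list(variants)
    nonsyn = sum(1 for v in variants if is_tmb_eligible(v, territory, min_depth))
    callable_mb = territory.total_megabases
    titv = None
    if capture_regions is not None:
        titv = titv_ratio(variants, capture_regions, min_depth)
    breadth = None
    if depth is not None and target is not None:
        breadth = breadth_of_coverage(depth, target, min_depth)
    return TmbReport(
        nonsyn_count=nonsyn,
        callable_mb=callable_mb,
        tmb=nonsyn / callable_mb,
        titv=titv,
        breadth_at_threshold=breadth,
    )


def _in_regions(v: SomaticVariant, regions: Sequence[Interval]) -> bool:
    return any(
        iv.contig == v.chrom and iv.start + 1 <= v.pos <= iv.end for iv in regions
    )


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS


def titv_ratio(
    variants: Iterable[SomaticVariant],
    regions: Sequence[Interval],
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> float | None:
    """Transition/transversion ratio over PASS, depth-qualified biallelic SNVs
    inside the capture regions. None when there are no transversions."""
    transitions = transversions = 0
    for v in variants:
        if len(v.ref_allele) != 1 or len(v.alt_allele) != 1:
            continue  # SNVs only
        if not v.is_pass or v.tumor_depth < min_depth:
            continue
        if not _in_regions(v, regions):
            continue
        if is_transition(v.ref_allele, v.alt_allele):
            transitions += 1
        else:
            transversions += 1
    if transversions == 0:
        return None
    return transitions / transversions


TMB_REPORT_COLUMNS = [
    "sample",
    "nonsyn_count",
    "callable_bases",
    "callable_mb",
    "tmb",
    "titv",
    "breadth_at_threshold",
]


def write_tmb_table(reports: dict[str, TmbReport], path: str | Path) -> None:
    """One tab-separated summary row per sample."""
    with open(path, "w") as fh:
        fh.write("\t".join(TMB_REPORT_COLUMNS) + "\n")
        for sample in sorted(reports):
            r = reports[sample]
            titv = format(r.titv, ".6g") if r.titv is not None else "undefined"
            breadth = (
                format(r.breadth_at_threshold, ".6g")
                if r.breadth_at_threshold is not None
                else ""
            )
            fh.write(
                f"{sample}\t{r.nonsyn_count}\t{int(r.callable_mb * 1e6)}\t"
                f"{r.callable_mb:.6g}\t{r.tmb:.6g}\t{titv}\t{breadth}\n"
            )
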