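"""Fusion call filtering and abundance (FFPM) quantification."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import FusionRecord


@dataclass(frozen=True)
class FusionFilterConfig:
    """Support / confidence / frame gates applied before peptide generation.

    Support is disjunctive: junction reads OR discordant pairs may satisfy the
    minimum. Caller-side blacklists are assumed already applied upstream.
    """

    min_junction_support: int = 5
    required_confidence: frozenset[str] = frozenset({"high"})
    require_in_frame: bool = True

    def __post_init__(self) -> None:
        if self.min_junction_support < 0:
            raise ValueError("min_junction_support must be >= 0")


def filter_fusions(
    records: Iterable[FusionRecord], cfg: FusionFilterConfig = FusionFilterConfig()
) -> list[FusionRecord]:
    kept = []
    for r in records:
        if max(r.junction_reads, r.discordant_pairs) < cfg.min_junction_support:
            continue
        if r.confidence not in cfg.required_confidence:
            continue
        if cfg.require_in_frame and r.frame_status != "in_frame":
            continue
        kept.append(r)
    return kept


def fusion_support(r: FusionRecord, include_discordant: bool = True) -> int:
    """Support reads counted toward FFPM; discordant inclusion is configurable."""
    return r.junction_reads + (r.discordant_pairs if include_discordant else 0)


def compute_ffpm(support_reads: int, total_mapped_reads: int) -> float:
    """Fusion fragments per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    if support_reads < 0:
        raise ValueError("support_reads must be >= 0")
    return support_reads / total_mapped_reads * 1e6
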