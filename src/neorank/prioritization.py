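"""Multi-component neoepitope priority scoring and deterministic ranking.

The composite score is a bounded product scaled to 0-100:

    priority = 100 * L(rank) * tanh(expr/scale) * clonality * foreignness

where L is the logistic down-weighting of the binding %Rank (slope 5,
inflection at 2%), expression enters through a hyperbolic tangent, clonality
is the variant allele fraction (1.0 for fusions), and foreignness is derived
from the wild-type counterpart's binding (absent counterpart means maximally
foreign). Exact self-matches against the reference proteome and candidates
failing the expression gate score zero outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .binding import classify_binder
from .io_formats import ProteomeDb

DEFAULT_SLOPE = 5.0
DEFAULT_INFLECTION = 2.0
DEFAULT_TPM_SCALE = 10.0
DEFAULT_FFPM_SCALE = 2.0
DEFAULT_MIN_TPM = 1.0
DEFAULT_MIN_FFPM = 1.0

EXPRESSION_UNITS = ("TPM", "FFPM")


def logistic_rank_weight(
    rank_percent: float,
    slope: float = DEFAULT_SLOPE,
    inflection: float = DEFAULT_INFLECTION,
) -> float:
    """L(x) = 1 / (1 + e^{slope * (x - inflection)}), in (0, 1).

    L(inflection) = 0.5 exactly; strong binders (low %Rank) approach 1 and
    ranks above the inflection decay rapidly toward 0.
    """
    if not rank_percent > 0:
        raise ValueError("rank_percent must be > 0")
    y = slope * (rank_percent - inflection)
    # evaluate in the numerically stable direction
    if y >= 0:
        e = math.exp(-y)
        return e / (1.0 + e)
    return 1.0 / (1.0 + math.exp(y))


def expression_component(
    value: float,
    unit: str = "TPM",
    tpm_scale: float = DEFAULT_TPM_SCALE,
    ffpm_scale: float = DEFAULT_FFPM_SCALE,
) -> float:
    """tanh(value / scale), in [0, 1). The expression gate is applied separately."""
    if value < 0:
        raise ValueError(f"expression value must be >= 0, got {value}")
    if unit not in EXPRESSION_UNITS:
        raise ValueError(f"unknown expression unit {unit!r}")
    scale = tpm_scale if unit == "TPM" else ffpm_scale
    t = math.tanh(value / scale)
    # keep the codomain strictly below 1 even when tanh saturates in floats
    return t if t < 1.0 else math.nextafter(1.0, 0.0)


def expression_gate(
    value: float | None,
    source_type: str,
    min_tpm: float = DEFAULT_MIN_TPM,
    min_ffpm: float = DEFAULT_MIN_FFPM,
) -> bool:
    """TPM >= 1 for variant-derived peptides; FFPM >= minimum for fusions.

    A gene absent from the abundance table (value None) fails the gate.
    """
    if value is None:
        return False
    threshold = min_ffpm if source_type == "fusion" else min_tpm
    return value >= threshold


def clonality_component(source_type: str, vaf: float | None) -> float:
    """Variant VAF as a linear clonality weight; fusions are treated as clonal."""
    if source_type == "fusion":
        return 1.0
    if vaf is None or not 0 <= vaf <= 1:
        raise ValueError(f"VAF required in [0,1] for {source_type}, got {vaf}")
    return vaf


def self_similarity(peptide: str, proteome: ProteomeDb) -> bool:
    """True iff the peptide occurs verbatim anywhere in the reference proteome."""
    return proteome.contains(peptide)


def foreignness_component(
    rank_mut: float,
    rank_wt: float | None,
    slope: float = DEFAULT_SLOPE,
    inflection: float = DEFAULT_INFLECTION,
) -> tuple[float, float | None]:
    """(foreignness in [0,1], agretopicity index or None).

    The agretopicity index is rank_wt / rank_mut. Foreignness is
    1 - 0.5 * L(rank_wt): a strongly binding wild-type counterpart can at most
    halve the priority, while peptides with no counterpart (fusion,
    frameshift, indel) are maximally foreign (1.0, index absent).
    """
    if not rank_mut > 0:
        raise ValueError("rank_mut must be > 0")
    if rank_wt is None:
        return 1.0, None
    if not rank_wt > 0:
        raise ValueError("rank_wt must be > 0")
    index = rank_wt / rank_mut
    foreignness = 1.0 - 0.5 * logistic_rank_weight(rank_wt, slope, inflection)
    return foreignness, index


@dataclass(frozen=True)
class ScoreComponents:
    logistic_weight: float
    expression_component: float
    expression_value: float
    expression_unit: str
    clonality: float
    foreignness: float
    agretopicity_index: float | None = None
    self_match: bool = False
    gate_passed: bool = True

    def __post_init__(self) -> None:
        checks = {
            "logistic_weight": (self.logistic_weight, 0.0, 1.0),
            "expression_component": (self.expression_component, 0.0, 1.0),
            "clonality": (self.clonality, 0.0, 1.0),
            "foreignness": (self.foreignness, 0.0, 1.0),
        }
        for name, (value, lo, hi) in checks.items():
            if not lo <= value <= hi:
                raise ValueError(f"{name} out of [{lo},{hi}]: {value}")


def priority_score(c: ScoreComponents) -> float:
    """0 when self-matched or expression-gated; otherwise the bounded product on 0-100."""
    if c.self_match or not c.gate_passed:
        return 0.0
    return 100.0 * c.logistic_weight * c.expression_component * c.clonality * c.foreignness


@dataclass(frozen=True)
class ScoredNeoepitope:
    sample: str
    peptide: str
    source_type: str
    gene_label: str
    hla_allele: str
    rank_percent: float
    rank_percent_wt: float | None
    components: ScoreComponents
    priority: float = field(default=0.0)
    binder_class: str = field(default="non_binder")

    def __post_init__(self) -> None:
        if not 0 <= self.priority <= 100:
            raise ValueError(f"priority_score out of [0,100]: {self.priority}")


def score_candidate(
    sample: str,
    peptide: str,
    source_type: str,
    gene_label: str,
    hla_allele: str,
    rank_percent: float,
    rank_wt: float | None,
    expression_value: float | None,
    expression_unit: str,
    vaf: float | None,
    proteome: ProteomeDb,
    *,
    slope: float = DEFAULT_SLOPE,
    inflection: float = DEFAULT_INFLECTION,
    tpm_scale: float = DEFAULT_TPM_SCALE,
    ffpm_scale: float = DEFAULT_FFPM_SCALE,
    min_tpm: float = DEFAULT_MIN_TPM,
    min_ffpm: float = DEFAULT_MIN_FFPM,
    strong_cutoff: float = 0.5,
    weak_cutoff: float = 2.0,
) -> ScoredNeoepitope:
    """Assemble all score components for one peptide-allele pair."""
    gate = expression_gate(expression_value, source_type, min_tpm, min_ffpm)
    expr_value = expression_value if expression_value is not None else 0.0
    foreignness, agretopicity = foreignness_component(rank_percent, rank_wt, slope, inflection)
    components = ScoreComponents(
        logistic_weight=logistic_rank_weight(rank_percent, slope, inflection),
        expression_component=expression_component(expr_value, expression_unit, tpm_scale, ffpm_scale),
        expression_value=expr_value,
        expression_unit=expression_unit,
        clonality=clonality_component(source_type, vaf),
        foreignness=foreignness,
        agretopicity_index=agretopicity,
        self_match=self_similarity(peptide, proteome),
        gate_passed=gate,
    )
    return ScoredNeoepitope(
        sample=sample,
        peptide=peptide,
        source_type=source_type,
        gene_label=gene_label,
        hla_allele=hla_allele,
        rank_percent=rank_percent,
        rank_percent_wt=rank_wt,
        components=components,
        priority=priority_score(components),
        binder_class=classify_binder(rank_percent, strong_cutoff, weak_cutoff),
    )


def rank_candidates(scored: Iterable[ScoredNeoepitope]) -> list[ScoredNeoepitope]:
    """Deterministic final ordering.

    Descending priority; ties broken by ascending %Rank, then descending
    expression value, then lexicographic peptide and allele.
    """
    return sorted(
        scored,
        key=lambda s: (
            -s.priority,
            s.rank_percent,
            -s.components.expression_value,
            s.peptide,
            s.hla_allele,
        ),
    )


def scored_to_row(s: ScoredNeoepitope) -> dict:
    """Flatten to the documented candidates-table schema."""
    c = s.components
    return {
        "sample": s.sample,
        "source_type": s.source_type,
        "gene_label": s.gene_label,
        "peptide": s.peptide,
        "length": len(s.peptide),
        "hla_allele": s.hla_allele,
        "rank_percent": s.rank_percent,
        "rank_percent_wt": s.rank_percent_wt,
        "agretopicity_index": c.agretopicity_index,
        "expression_value": c.expression_value,
        "expression_unit": c.expression_unit,
        "clonality": c.clonality,
        "logistic_weight": c.logistic_weight,
        "expression_component": c.expression_component,
        "foreignness": c.foreignness,
        "self_match": c.self_match,
        "binder_class": s.binder_class,
        "priority_score": s.priority,
    }
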