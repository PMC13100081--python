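"""Pluggable peptide-MHC %Rank providers and binder classification.

The real neural-network predictor is never re-implemented: its output is
consumed through :func:`import_predictions` (or an external-command adapter
outside the test surface). The deterministic stub exists so the rest of the
engine is testable with no licensed tool.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

from .io_formats import FormatError

STRONG_RANK_CUTOFF = 0.5
WEAK_RANK_CUTOFF = 2.0

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class BindingScore:
    peptide: str
    allele: str
    rank_percent: float

    def __post_init__(self) -> None:
        if not self.rank_percent > 0:
            raise ValueError(f"rank_percent must be > 0, got {self.rank_percent}")


def _digest(*parts: str) -> int:
    h = hashlib.sha256("|".join(parts).encode("ascii")).digest()
    return int.from_bytes(h[:8], "big")


def anchor_pair(allele: str) -> tuple[str, str]:
    """Allele-keyed (position-2, C-terminal) anchor residues used by the stub.

    Exposed so tests and the fixtures generator can plant strong binders.
    """
    d = _digest("anchor", allele)
    return _AA20[d % 20], _AA20[(d // 20) % 20]


def stub_predict(
    peptides: Iterable[str],
    alleles: Iterable[str],
    motif_bonus: float = 0.002,
) -> list[BindingScore]:
    """Deterministic pseudo-%Rank in (0, 100] from a digest of (peptide, allele).

    Peptides whose anchor positions (2 and C-terminus) match the allele's
    anchor pair have their rank multiplied by ``motif_bonus``, making them
    strong binders; everything else is approximately uniform on (0, 100].
    """
    if not 0 < motif_bonus <= 1:
        raise ValueError("motif_bonus must be in (0, 1]")
    scores = []
    for allele in alleles:
        a2, ac = anchor_pair(allele)
        for pep in peptides:
            base = ((_digest("rank", pep, allele) % 10**9) + 1) / 10**9 * 100.0
            if len(pep) >= 2 and pep[1] == a2 and pep[-1] == ac:
                base *= motif_bonus
            scores.append(BindingScore(peptide=pep, allele=allele, rank_percent=base))
    return scores


@dataclass(frozen=True)
class StubPredictor:
    """Registry entry for the digest-based test double."""

    name: str = "stub"
    deterministic: bool = True
    motif_bonus: float = 0.002

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[BindingScore]:
        return stub_predict(peptides, alleles, self.motif_bonus)


PREDICTORS = {"stub": StubPredictor()}


def get_predictor(name: str):
    try:
        return PREDICTORS[name]
    except KeyError:
        raise KeyError(f"unknown predictor {name!r}; available: {sorted(PREDICTORS)}")


class ImportResult(NamedTuple):
    scores: list[BindingScore]
    missing: list[tuple[str, str]]


_PEPTIDE_COLS = ("peptide", "Peptide")
_ALLELE_COLS = ("allele", "MHC", "HLA", "mhc")
_RANK_COLS = ("%Rank_EL", "%Rank_BA", "%Rank", "rank_percent", "Rank", "rank")


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    for c in candidates:
        if c in df.columns:
            return c
    raise FormatError(f"prediction table has no {what} column (looked for {candidates})")


def import_predictions(
    path: str | Path,
    expected_pairs: Iterable[tuple[str, str]] | None = None,
) -> ImportResult:
    """Read a NetMHCpan-4.x-style tabular file of (peptide, allele, %Rank).

    Whatever %Rank column is present is treated as authoritative. Duplicate
    rows for one pair with conflicting ranks are a hard error; pairs expected
    but absent are returned in ``missing``.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    pep_col = _pick_column(df, _PEPTIDE_COLS, "peptide")
    allele_col = _pick_column(df, _ALLELE_COLS, "allele")
    rank_col = _pick_column(df, _RANK_COLS, "%Rank")

    # iterrows, not itertuples: '%Rank' is not a valid attribute name
    by_pair: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        pair = (str(row[pep_col]), str(row[allele_col]))
        rank = float(row[rank_col])
        if pair in by_pair and by_pair[pair] != rank:
            raise FormatError(f"conflicting duplicate rows for {pair}")
        by_pair[pair] = rank

    scores = [
        BindingScore(peptide=p, allele=a, rank_percent=r) for (p, a), r in by_pair.items()
    ]
    missing: list[tuple[str, str]] = []
    if expected_pairs is not None:
        missing = [pair for pair in expected_pairs if pair not in by_pair]
    return ImportResult(scores=scores, missing=missing)


def write_predictions(scores: Iterable[BindingScore], path: str | Path) -> None:
    """Write scores in the dialect read back by :func:`import_predictions`."""
    with open(path, "w") as fh:
        fh.write("Peptide\tMHC\t%Rank_EL\n")
        for s in scores:
            fh.write(f"{s.peptide}\t{s.allele}\t{s.rank_percent!r}\n")


def classify_binder(
    rank_percent: float,
    strong_cutoff: float = STRONG_RANK_CUTOFF,
    weak_cutoff: float = WEAK_RANK_CUTOFF,
) -> str:
    """strong iff rank < 0.5; weak iff 0.5 <= rank <= 2.0; non_binder above."""
    if not rank_percent > 0:
        raise ValueError("rank_percent must be > 0")
    if rank_percent < strong_cutoff:
        return "strong"
    if rank_percent <= weak_cutoff:
        return "weak"
    return "non_binder"
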