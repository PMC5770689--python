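"""Secretory-pathway targeting summaries and chi-square enrichment.

A protein is classed as secretory-pathway targeting (SP-targeting) if it
carries a signal peptide OR at least one transmembrane domain — the union,
counted once. Flags are inputs (from upstream predictors), never computed
from sequence here. Group summaries report counts and percentages rounded
half-up to one decimal; enrichment between groups is tested with a Pearson
chi-square on a 2x2 table (Yates continuity correction available, off by
default). Groups may overlap (e.g. upregulated within regulated), so the
assignment maps each protein to a *set* of group labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnnotationRecord",
    "TargetingSummary",
    "classify_sp_targeting",
    "summarize_targeting",
    "chi_square_test",
]


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    has_signal_peptide: bool
    has_transmembrane: bool


@dataclass(frozen=True)
class TargetingSummary:
    group_label: str
    n: int
    n_sp: int
    n_tm: int
    n_both: int
    n_targeting: int
    pct_sp: float | None
    pct_tm: float | None
    pct_targeting: float | None
    frac_sp: float | None
    frac_tm: float | None
    frac_targeting: float | None


def classify_sp_targeting(record: AnnotationRecord) -> bool:
    """True iff the protein has a signal peptide or a transmembrane domain."""
    return record.has_signal_peptide or record.has_transmembrane


def _pct(count: int, n: int) -> float:
    # percentage rounded half-up to one decimal, as in printed tables
    return float(
        (Decimal(100) * Decimal(count) / Decimal(n)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_targeting(
    records: Sequence[AnnotationRecord],
    group_assignment: Mapping[str, Iterable[str]],
    group_order: Sequence[str] | None = None,
) -> list[TargetingSummary]:
    """Per-group SP/TM/union counts and percentages.

    ``group_assignment`` maps protein_id to the group labels it belongs to
    (groups may overlap). Empty groups get n=0 with undefined (None)
    percentages.
    """
    by_group: dict[str, list[AnnotationRecord]] = {}
    if group_order is not None:
        for g in group_order:
            by_group[g] = []
    for rec in records:
        for g in group_assignment.get(rec.protein_id, ()):
            by_group.setdefault(g, []).append(rec)

    out = []
    for g, recs in by_group.items():
        n = len(recs)
        n_sp = sum(r.has_signal_peptide for r in recs)
        n_tm = sum(r.has_transmembrane for r in recs)
        n_both = sum(r.has_signal_peptide and r.has_transmembrane for r in recs)
        n_tgt = n_sp + n_tm - n_both
        if n == 0:
            out.append(TargetingSummary(g, 0, 0, 0, 0, 0, *([None] * 6)))
            continue
        out.append(
            TargetingSummary(
                g, n, n_sp, n_tm, n_both, n_tgt,
                _pct(n_sp, n), _pct(n_tm, n), _pct(n_tgt, n),
                n_sp / n, n_tm / n, n_tgt / n,
            )
        )
    return out


def chi_square_test(
    table: Sequence[Sequence[float]], continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, 1 df.

    Optional Yates continuity correction (off by default). A zero row or
    column margin makes expected counts zero and is rejected with an error
    naming the degenerate margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    for name, margin in (("row", rows), ("column", cols)):
        if (margin == 0).any():
            idx = int(np.flatnonzero(margin == 0)[0])
            raise ValueError(f"degenerate {name} margin at index {idx} (zero total)")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=continuity)
    return float(stat), float(p)
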