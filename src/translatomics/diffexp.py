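"""Differential protein-synthesis calling from pulsed-SILAC ratio tables.

Each biological replicate contributes one log2(mutant/wt) ratio per protein.
Because isotope labels are reversed in half the replicates (label swap), the
table first gets oriented so every column means log2(mutant/wt); proteins
detected in fewer than ``min_reps`` replicates are filtered; the rest are
tested with a two-sided one-sample t-test of the oriented log2 ratios
against zero. Significance is called at raw p < alpha (a Benjamini–Hochberg
FDR column is emitted as supplementary output but does not drive status).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantTable",
    "DifferentialResult",
    "orient_ratios",
    "filter_detected",
    "test_differential",
    "volcano_coords",
    "summarize_regulation",
    "results_to_frame",
]

ORIENTATIONS = ("standard", "swapped")


@dataclass(frozen=True)
class QuantTable:
    """Per-protein replicate log2 ratios with per-replicate label orientation.

    ``data``: DataFrame indexed by protein_id, one column per replicate,
    NaN = not detected. ``orientation``: replicate name -> "standard"
    (columns already mean log2(mutant/wt)) or "swapped" (label-reversed
    replicate, stored as log2(wt/mutant)).
    """

    data: pd.DataFrame
    orientation: dict[str, str]

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 replicates")
        for col in self.data.columns:
            o = self.orientation.get(col)
            if o not in ORIENTATIONS:
                raise ValueError(f"replicate {col!r}: unknown orientation {o!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValueError("non-finite ratio values present")


@dataclass(frozen=True)
class DifferentialResult:
    protein_id: str
    n_detected: int
    mean_log2fc: float
    t_stat: float
    p_value: float
    bh_fdr: float
    status: str  # up | down | ns | filtered | degenerate


def orient_ratios(table: QuantTable) -> QuantTable:
    """Negate label-swapped columns so every column means log2(mutant/wt)."""
    data = table.data.copy()
    for col in data.columns:
        if table.orientation[col] == "swapped":
            data[col] = -data[col]
    return QuantTable(data, {c: "standard" for c in data.columns})


def filter_detected(
    table: QuantTable, min_reps: int = 3
) -> tuple[QuantTable, list[DifferentialResult]]:
    """Split into proteins detected in >= min_reps replicates and the rest.

    Filtered proteins are returned as results with status ``"filtered"``.
    """
    n_rep = table.data.shape[1]
    if min_reps > n_rep:
        raise ValueError(f"min_reps={min_reps} exceeds replicate count {n_rep}")
    n_det = table.data.notna().sum(axis=1)
    keep = n_det >= min_reps
    filtered = [
        DifferentialResult(pid, int(n), math.nan, math.nan, math.nan, math.nan, "filtered")
        for pid, n in n_det[~keep].items()
    ]
    return QuantTable(table.data.loc[keep], dict(table.orientation)), filtered


def test_differential(table: QuantTable, alpha: float = 0.05) -> list[DifferentialResult]:
    """One-sample t-test of each protein's oriented log2 ratios against 0.

    df = n_detected - 1. Proteins with fewer than two values, or with zero
    variance around a non-zero mean, cannot be tested and get status
    ``"degenerate"`` (undefined p). All-zero rows are the exact null:
    t = 0, p = 1. Status is up/down by sign of the mean when p < alpha.
    """
    rows = []
    for pid, row in table.data.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean()) if n else math.nan
        if n < 2:
            rows.append((pid, n, mean, math.nan, math.nan, "degenerate"))
            continue
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            if mean == 0.0:
                rows.append((pid, n, 0.0, 0.0, 1.0, "ns"))
            else:
                rows.append((pid, n, mean, math.nan, math.nan, "degenerate"))
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        status = "ns"
        if p < alpha:
            status = "up" if mean > 0 else "down"
        rows.append((pid, n, mean, float(t), float(p), status))

    # supplementary BH-FDR over the testable proteins
    pvals = np.array([r[4] for r in rows])
    testable = ~np.isnan(pvals)
    fdr = np.full(pvals.shape, math.nan)
    if testable.any():
        fdr[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    return [
        DifferentialResult(pid, n, mean, t, p, float(q), status)
        for (pid, n, mean, t, p, status), q in zip(rows, fdr)
    ]


def volcano_coords(results: list[DifferentialResult]) -> list[tuple[float, float]]:
    """(log2 fold change, -log10 p) per tested protein.

    A linear fold change of 2 maps to x = 1; p = 0.05 maps to
    y = -log10(0.05) ~ 1.301. Filtered and degenerate proteins carry no
    point.
    """
    return [
        (r.mean_log2fc, -math.log10(r.p_value))
        for r in results
        if r.status in ("up", "down", "ns")
    ]


def summarize_regulation(results: list[DifferentialResult]) -> dict[str, int]:
    """Counts of tested / up / down proteins."""
    statuses = [r.status for r in results]
    return {
        "n_tested": sum(s in ("up", "down", "ns") for s in statuses),
        "n_up": statuses.count("up"),
        "n_down": statuses.count("down"),
    }


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.protein_id, r.n_detected, r.mean_log2fc, r.t_stat, r.p_value, r.bh_fdr, r.status)
            for r in results
        ],
        columns=["protein_id", "n_detected", "mean_log2fc", "t_stat", "p_value", "bh_fdr", "status"],
    )
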