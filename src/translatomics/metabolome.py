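"""Metabolite peak-table normalization and presence / uptake calls.

Peak intensities are median-normalized per sample (every sample's median
over its detected metabolites is scaled to the global median of sample
medians). Presence in a genotype's cells requires at least ``min_fraction``
of that genotype's replicates above a detection threshold at *every*
timepoint ("consistently detected"); genotype-restricted patterns such as a
mutant-only metabolite fall out of the two per-genotype calls. Medium
metabolites are classed as consumed or secreted by comparing conditioned to
unconditioned medium beyond a relative margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "PresenceCall",
    "median_normalize",
    "default_threshold",
    "presence_calls",
    "uptake_secretion",
]

GENOTYPES = ("wt", "mutant", "none")
COMPARTMENTS = ("cell", "medium", "unconditioned")


@dataclass(frozen=True)
class PeakTable:
    """Metabolite x sample intensity matrix with per-sample metadata.

    ``data``: DataFrame indexed by metabolite, one column per sample_id;
    intensity 0 means undetected. ``meta``: DataFrame indexed by sample_id
    with columns genotype (wt|mutant|none), compartment
    (cell|medium|unconditioned) and timepoint (hours). Unconditioned medium
    has genotype "none".
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(self.meta.index):
            missing = set(self.data.columns) ^ set(self.meta.index)
            raise ValueError(f"sample metadata mismatch: {sorted(missing)}")
        bad = set(self.meta["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        bad = set(self.meta["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative intensities present")

    def select(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.meta.index)
        for key, value in criteria.items():
            mask &= self.meta[key] == value
        return list(self.meta.index[mask])


@dataclass(frozen=True)
class PresenceCall:
    metabolite: str
    pattern: str  # both | wt-only | mutant-only | neither
    consistent_across_timepoints: bool


def median_normalize(table: PeakTable) -> PeakTable:
    """Scale each sample so sample medians (over detected peaks) are equal.

    The common target is the median of the per-sample medians, so a table
    whose medians already agree is returned unchanged (idempotent). A
    sample with no detected metabolite cannot be scaled and is an error.
    """
    data = table.data.copy().astype(float)
    medians = {}
    for s in data.columns:
        nonzero = data[s][data[s] > 0]
        if nonzero.empty:
            raise ValueError(f"sample {s!r} has no detected metabolites")
        medians[s] = float(nonzero.median())
    target = float(np.median(list(medians.values())))
    for s in data.columns:
        data[s] *= target / medians[s]
    return PeakTable(data, table.meta)


def default_threshold(table: PeakTable) -> float:
    """Half the smallest nonzero intensity — everything detected stays detected."""
    values = table.data.to_numpy()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("table has no detected intensities")
    return 0.5 * float(nonzero.min())


def _detected(
    table: PeakTable, samples: list[str], threshold: float, min_fraction: float
) -> pd.Series:
    sub = table.data[samples]
    return (sub > threshold).sum(axis=1) >= min_fraction * len(samples)


def presence_calls(
    table: PeakTable,
    threshold: float | None = None,
    min_fraction: float = 1.0,
) -> list[PresenceCall]:
    """Per-metabolite genotype presence pattern in the cell compartment.

    A metabolite is detected in a genotype at a timepoint when at least
    ``min_fraction`` of that genotype's cell replicates exceed
    ``threshold`` (default: half the smallest nonzero intensity). The
    overall pattern requires detection at every timepoint;
    ``consistent_across_timepoints`` is True iff the per-timepoint patterns
    are all identical.
    """
    if threshold is None:
        threshold = default_threshold(table)
    timepoints = sorted(
        set(table.meta.loc[table.meta["compartment"] == "cell", "timepoint"])
    )
    if not timepoints:
        raise ValueError("no cell-compartment samples in table")
    per_tp: dict[float, pd.DataFrame] = {}
    for tp in timepoints:
        cols = {}
        for g in ("wt", "mutant"):
            samples = table.select(compartment="cell", genotype=g, timepoint=tp)
            if not samples:
                raise ValueError(f"no cell samples for genotype {g!r} at t={tp}")
            cols[g] = _detected(table, samples, threshold, min_fraction)
        per_tp[tp] = pd.DataFrame(cols)

    def pattern(wt: bool, mut: bool) -> str:
        if wt and mut:
            return "both"
        if wt:
            return "wt-only"
        if mut:
            return "mutant-only"
        return "neither"

    calls = []
    for m in table.data.index:
        tp_patterns = [
            pattern(per_tp[tp].loc[m, "wt"], per_tp[tp].loc[m, "mutant"])
            for tp in timepoints
        ]
        wt_all = all(per_tp[tp].loc[m, "wt"] for tp in timepoints)
        mut_all = all(per_tp[tp].loc[m, "mutant"] for tp in timepoints)
        calls.append(
            PresenceCall(m, pattern(wt_all, mut_all), len(set(tp_patterns)) == 1)
        )
    return calls


def uptake_secretion(table: PeakTable, margin: float = 0.2) -> pd.DataFrame:
    """Classify medium metabolites as consumed / secreted / unchanged.

    Per genotype, the mean conditioned-medium intensity is compared to the
    mean over unconditioned-medium references: below (1 - margin) times the
    reference is consumed, above (1 + margin) times is secreted, else
    unchanged. A metabolite absent from unconditioned medium but present in
    conditioned medium is secreted.
    """
    ref_samples = table.select(compartment="unconditioned")
    if not ref_samples:
        raise ValueError("missing unconditioned-medium reference samples")
    ref = table.data[ref_samples].mean(axis=1)
    out = {}
    for g in ("wt", "mutant"):
        samples = table.select(compartment="medium", genotype=g)
        if not samples:
            raise ValueError(f"no conditioned-medium samples for genotype {g!r}")
        cond = table.data[samples].mean(axis=1)
        calls = []
        for m in table.data.index:
            r, c = float(ref[m]), float(cond[m])
            if r == 0:
                calls.append("secreted" if c > 0 else "unchanged")
            elif c < (1 - margin) * r:
                calls.append("consumed")
            elif c > (1 + margin) * r:
                calls.append("secreted")
            else:
                calls.append("unchanged")
        out[g] = calls
    return pd.DataFrame(out, index=table.data.index)
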