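"""Variant-proportional aggregation of UTR features and group comparisons.

A protein may be translated from several mRNA variants. So that proteins
with many variants do not dominate group-level feature distributions, each
variant contributes weight 1/k, where k is the protein's number of
*included* variants (variants excluded for short UTRs are dropped before
weighting, so weights always sum to 1 per protein; recomputing k over the
survivors is a documented choice, switchable via ``recompute_k``).

Group differences in a binned feature are tested either by the classical
Pearson chi-square on half-up-rounded weighted counts ("chi-square-rounded",
for comparability with spreadsheet-style analyses) or — the default, since
chi-square on non-integer weighted counts is improper — by a permutation
test that shuffles group labels over proteins and uses the chi-square
statistic on the unrounded weighted table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .utr import UTRFeatures

__all__ = [
    "ProteinFeatureProfile",
    "BinnedComparison",
    "LENGTH_EDGES",
    "UORF_MAX_BIN",
    "build_profiles",
    "bin_feature",
    "compare_groups",
]

# default length bins: [13,150), [150,550], (550, inf)
LENGTH_EDGES: tuple[float, ...] = (13.0, 150.0, 550.0)
# default uORF-count bins: 0,1,...,7 and ">=8"
UORF_MAX_BIN = 8


@dataclass
class ProteinFeatureProfile:
    protein_id: str
    group: str
    variants: list[UTRFeatures] = field(default_factory=list)

    @property
    def weight_per_variant(self) -> float:
        return 1.0 / len(self.variants)


def build_profiles(
    features: Sequence[UTRFeatures],
    protein_groups: Mapping[str, str],
    recompute_k: bool = True,
) -> tuple[list[ProteinFeatureProfile], list[str]]:
    """Group variant features by protein and assign proportional weights.

    Returns (profiles, dropped) where ``dropped`` logs proteins with no
    included variant (all excluded, or no transcript). With
    ``recompute_k=False`` the weight denominator counts excluded variants
    too (weights then sum to < 1 for proteins with exclusions).
    """
    by_protein: dict[str, list[UTRFeatures]] = {}
    for f in features:
        by_protein.setdefault(f.protein_id, []).append(f)

    profiles, dropped = [], []
    for pid, group in protein_groups.items():
        variants = by_protein.get(pid, [])
        included = [v for v in variants if not v.excluded]
        if not included:
            dropped.append(pid)
            continue
        prof = ProteinFeatureProfile(pid, group, included)
        if not recompute_k and len(variants) != len(included):
            # keep 1/k over all variants by padding weight bookkeeping
            prof._k_total = len(variants)  # type: ignore[attr-defined]
        profiles.append(prof)
    return profiles, dropped


def _weight(profile: ProteinFeatureProfile) -> float:
    k = getattr(profile, "_k_total", len(profile.variants))
    return 1.0 / k


def _bin_index(value: float, inner: np.ndarray) -> int:
    # bins: [e0, e1), [e1, e2], (e2, inf) style — overflow only strictly
    # beyond the last inner edge
    idx = int(np.searchsorted(inner, value, side="right"))
    if idx == len(inner) and value == inner[-1]:
        idx -= 1
    return idx


def _bin_labels(feature_name: str, edges: Sequence[float] | None) -> tuple[list[str], object]:
    if feature_name == "uorf_count" and edges is None:
        labels = [str(i) for i in range(UORF_MAX_BIN)] + [f">={UORF_MAX_BIN}"]
        return labels, None
    if edges is None:
        if feature_name != "length":
            raise ValueError(f"explicit edges required for feature {feature_name!r}")
        edges = LENGTH_EDGES
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    inner = np.asarray(edges[1:])
    labels = [f"[{edges[0]:g},{edges[1]:g})"]
    labels += [f"[{a:g},{b:g}]" for a, b in zip(edges[1:-1], edges[2:])]
    labels += [f">({edges[-1]:g})"]
    return labels, (edges[0], inner)


def _variant_value(variant: UTRFeatures, feature_name: str) -> float:
    value = getattr(variant, feature_name)
    if value is None:
        raise ValueError(
            f"variant {variant.transcript_id} has no {feature_name!r} value"
        )
    return float(value)


def _protein_rows(
    profiles: Sequence[ProteinFeatureProfile],
    feature_name: str,
    edges: Sequence[float] | None,
) -> tuple[np.ndarray, list[str]]:
    """Per-protein weighted bin-mass rows (n_proteins x n_bins)."""
    labels, parsed = _bin_labels(feature_name, edges)
    rows = np.zeros((len(profiles), len(labels)))
    for r, prof in enumerate(profiles):
        w = _weight(prof)
        for v in prof.variants:
            value = _variant_value(v, feature_name)
            if parsed is None:  # integer uORF binning
                idx = min(int(value), UORF_MAX_BIN)
            else:
                e0, inner = parsed
                if value < e0:
                    raise ValueError(
                        f"value {value} below first edge {e0} "
                        f"(transcript {v.transcript_id})"
                    )
                idx = _bin_index(value, inner)
            rows[r, idx] += w
    return rows, labels


def bin_feature(
    profiles: Sequence[ProteinFeatureProfile],
    feature_name: str,
    edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Weighted histogram of a feature, one row per group.

    Each variant contributes its protein weight to the bin holding its
    value, so every row sums to the group's protein count. Continuous
    features use edges ``(e0, ..., em)`` read as [e0,e1), middle bins
    closed, and an open overflow bin beyond em; a value below e0 is an
    error (such variants should have been excluded upstream). The
    ``uorf_count`` default bins integer counts 0..7 with a ">=8" tail.
    """
    rows, labels = _protein_rows(profiles, feature_name, edges)
    groups = sorted({p.group for p in profiles})
    counts = pd.DataFrame(0.0, index=groups, columns=labels)
    for prof, row in zip(profiles, rows):
        counts.loc[prof.group] += row
    return counts


@dataclass
class BinnedComparison:
    feature_name: str
    bin_labels: list[str]
    weighted_counts: pd.DataFrame
    chi2_stat: float
    p_value: float
    method: str
    n_perm: int | None = None


def _pearson_stat(table: np.ndarray) -> float:
    """Pearson chi-square statistic of an r x c table; zero-total columns dropped."""
    tab = table[:, table.sum(axis=0) > 0]
    total = tab.sum()
    if total == 0:
        return 0.0
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (tab - expected) ** 2 / expected
    return float(np.nansum(terms))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.array(
        [[int(Decimal(v).quantize(Decimal(1), rounding=ROUND_HALF_UP)) for v in row] for row in x],
        dtype=float,
    )


def compare_groups(
    profiles: Sequence[ProteinFeatureProfile],
    feature_name: str,
    edges: Sequence[float] | None = None,
    method: str = "permutation",
    n_perm: int = 10000,
    seed: int | None = None,
) -> BinnedComparison:
    """Test whether a binned feature distribution differs between two groups.

    method "permutation" (default): chi-square statistic on the unrounded
    weighted table; the null distribution comes from shuffling group labels
    over proteins; p = (1 + #{perm >= obs}) / (1 + n_perm).

    method "chi-square-rounded": weighted counts rounded half-up to
    integers, then a classical Pearson chi-square with the asymptotic
    p-value.
    """
    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    observed = bin_feature(profiles, feature_name, edges)
    if (observed.sum(axis=1) == 0).any():
        raise ValueError("a group has zero mass")
    labels = list(observed.columns)

    if method == "chi-square-rounded":
        rounded = _round_half_up(observed.to_numpy())
        stat = _pearson_stat(rounded)
        dof = (rounded.shape[0] - 1) * ((rounded.sum(axis=0) > 0).sum() - 1)
        p = float(stats.chi2.sf(stat, max(dof, 1)))
        return BinnedComparison(feature_name, labels, observed, stat, p, method)

    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    # per-protein bin-mass rows, then shuffle the group label vector
    rows, _ = _protein_rows(profiles, feature_name, edges)
    labels_vec = np.array([p.group == groups[1] for p in profiles])

    def stat_for(mask: np.ndarray) -> float:
        table = np.vstack([rows[~mask].sum(axis=0), rows[mask].sum(axis=0)])
        return _pearson_stat(table)

    obs_stat = stat_for(labels_vec)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels_vec.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat_for(perm) >= obs_stat - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return BinnedComparison(feature_name, labels, observed, obs_stat, p, method, n_perm)
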