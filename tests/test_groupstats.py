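"""Variant-proportional weighting, binning and the two group comparisons."""

import numpy as np
import pytest

from translatomics.groupstats import (
    LENGTH_EDGES,
    bin_feature,
    build_profiles,
    compare_groups,
)
from translatomics.utr import UTRFeatures


def feat(pid, tid, length=100, gc=50.0, uorfs=0, excluded=False):
    return UTRFeatures(
        tid, pid, length, gc_percent=gc, uorf_count=uorfs,
        excluded=excluded, reason="min_length" if excluded else "",
    )


class TestProfiles:
    def test_two_variants_get_half_weight_each(self):
        profiles, _ = build_profiles(
            [feat("P1", "t1"), feat("P1", "t2")], {"P1": "regulated"}
        )
        assert profiles[0].weight_per_variant == 0.5

    def test_excluded_variant_dropped_before_weighting(self):
        feats = [feat("P1", "t1"), feat("P1", "t2"), feat("P1", "t3", excluded=True)]
        profiles, _ = build_profiles(feats, {"P1": "regulated"})
        assert len(profiles[0].variants) == 2
        assert profiles[0].weight_per_variant == 0.5

    def test_single_variant_weight_one(self):
        profiles, _ = build_profiles([feat("P1", "t1")], {"P1": "regulated"})
        assert profiles[0].weight_per_variant == 1.0

    def test_protein_without_included_variant_logged(self):
        feats = [feat("P1", "t1", excluded=True)]
        profiles, dropped = build_profiles(
            feats, {"P1": "regulated", "P2": "non-regulated"}
        )
        assert not profiles and sorted(dropped) == ["P1", "P2"]


class TestBinning:
    def test_length_bins_split_variant_mass(self):
        feats = [feat("P1", "t1", length=100), feat("P1", "t2", length=600)]
        profiles, _ = build_profiles(feats, {"P1": "regulated"})
        counts = bin_feature(profiles, "length", LENGTH_EDGES)
        assert counts.iloc[0].tolist() == [0.5, 0.0, 0.5]

    def test_edge_values_follow_printed_bin_convention(self):
        # <150 is the short bin, >550 the long bin; 150 and 550 stay middle
        feats = [
            feat("P1", "t1", length=149), feat("P2", "t2", length=150),
            feat("P3", "t3", length=550), feat("P4", "t4", length=551),
        ]
        profiles, _ = build_profiles(feats, {f"P{i}": "g" for i in range(1, 5)})
        counts = bin_feature(profiles, "length", LENGTH_EDGES)
        assert counts.iloc[0].tolist() == [1.0, 2.0, 1.0]

    def test_uorf_counts_bin_integers_with_8plus_tail(self):
        feats = [feat("P1", "t1", uorfs=0), feat("P2", "t2", uorfs=8), feat("P3", "t3", uorfs=12)]
        profiles, _ = build_profiles(feats, {f"P{i}": "g" for i in range(1, 4)})
        counts = bin_feature(profiles, "uorf_count")
        assert counts.loc["g", "0"] == 1.0
        assert counts.loc["g", ">=8"] == 2.0

    def test_value_below_first_edge_rejected(self):
        profiles, _ = build_profiles([feat("P1", "t1", length=5)], {"P1": "g"})
        with pytest.raises(ValueError, match="below first edge"):
            bin_feature(profiles, "length", LENGTH_EDGES)

    def test_mass_conservation_per_group(self):
        rng = np.random.default_rng(11)
        feats, groups = [], {}
        for i in range(60):
            pid = f"P{i}"
            groups[pid] = "regulated" if i % 3 == 0 else "non-regulated"
            for v in range(int(rng.integers(1, 4))):
                feats.append(feat(pid, f"{pid}.{v}", length=int(rng.integers(13, 900))))
        profiles, _ = build_profiles(feats, groups)
        counts = bin_feature(profiles, "length", LENGTH_EDGES)
        sizes = {"regulated": 20, "non-regulated": 40}
        for g, total in counts.sum(axis=1).items():
            assert total == pytest.approx(sizes[g], abs=1e-9)

    def test_histogram_matches_per_variant_accumulation(self):
        rng = np.random.default_rng(11)
        feats, groups = [], {}
        for i in range(40):
            pid = f"P{i}"
            groups[pid] = "a" if i % 2 else "b"
            for v in range(int(rng.integers(1, 5))):
                feats.append(feat(pid, f"{pid}.{v}", length=int(rng.integers(13, 900))))
        profiles, _ = build_profiles(feats, groups)
        counts = bin_feature(profiles, "length", LENGTH_EDGES)
        # independent accumulation loop
        expected = {g: [0.0, 0.0, 0.0] for g in ("a", "b")}
        by_pid = {}
        for f in feats:
            by_pid.setdefault(f.protein_id, []).append(f)
        for pid, fl in by_pid.items():
            w = 1.0 / len(fl)
            for f in fl:
                if f.length < 150:
                    b = 0
                elif f.length <= 550:
                    b = 1
                else:
                    b = 2
                expected[groups[pid]][b] += w
        for g in ("a", "b"):
            assert counts.loc[g].tolist() == pytest.approx(expected[g], abs=1e-9)


def _two_group_profiles(rng, n_per_group, mean_a=150.0, mean_b=150.0):
    feats, groups = [], {}
    for i in range(2 * n_per_group):
        pid = f"P{i}"
        group = "a" if i < n_per_group else "b"
        groups[pid] = group
        mean = mean_a if group == "a" else mean_b
        k = int(rng.integers(1, 4))
        for v in range(k):
            length = max(13, int(rng.lognormal(np.log(mean), 0.8)))
            feats.append(feat(pid, f"{pid}.{v}", length=length))
    profiles, _ = build_profiles(feats, groups)
    return profiles


class TestComparison:
    def test_identical_distributions_give_zero_stat_and_p_one(self):
        feats = [feat("P1", "t1", length=100), feat("P2", "t2", length=100)]
        profiles, _ = build_profiles(feats, {"P1": "a", "P2": "b"})
        cmp = compare_groups(profiles, "length", LENGTH_EDGES, n_perm=200, seed=1)
        assert cmp.chi2_stat == 0.0
        assert cmp.p_value == 1.0

    def test_planted_length_shift_detected(self):
        rng = np.random.default_rng(2)
        profiles = _two_group_profiles(rng, 100, mean_a=150.0, mean_b=300.0)
        cmp = compare_groups(profiles, "length", LENGTH_EDGES, n_perm=499, seed=2)
        assert cmp.p_value < 0.05

    def test_permutation_p_invariant_to_labels_and_order(self):
        rng = np.random.default_rng(4)
        profiles = _two_group_profiles(rng, 40, mean_a=150.0, mean_b=260.0)
        cmp1 = compare_groups(profiles, "length", LENGTH_EDGES, n_perm=300, seed=9)
        renamed = [
            type(p)(p.protein_id, {"a": "x", "b": "y"}[p.group], p.variants)
            for p in profiles
        ]
        cmp2 = compare_groups(renamed, "length", LENGTH_EDGES, n_perm=300, seed=9)
        assert cmp1.p_value == cmp2.p_value
        reordered = list(reversed(profiles))
        cmp3 = compare_groups(reordered, "length", LENGTH_EDGES, n_perm=300, seed=9)
        assert cmp1.chi2_stat == pytest.approx(cmp3.chi2_stat, abs=1e-9)

    def test_single_variant_weighted_equals_unweighted_chi2(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(6)
        feats, groups = [], {}
        for i in range(80):
            pid = f"P{i}"
            groups[pid] = "a" if i % 2 else "b"
            feats.append(feat(pid, f"{pid}.0", length=int(rng.integers(13, 900))))
        profiles, _ = build_profiles(feats, groups)
        cmp = compare_groups(
            profiles, "length", LENGTH_EDGES, method="chi-square-rounded"
        )
        table = cmp.weighted_counts.to_numpy()
        stat, p, _, _ = chi2_contingency(table[:, table.sum(axis=0) > 0], correction=False)
        assert cmp.chi2_stat == pytest.approx(stat, rel=1e-10)
        assert cmp.p_value == pytest.approx(p, rel=1e-10)

    def test_zero_mass_group_rejected(self):
        profiles, _ = build_profiles([feat("P1", "t1")], {"P1": "a"})
        with pytest.raises(ValueError, match="two groups"):
            compare_groups(profiles, "length", LENGTH_EDGES)
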