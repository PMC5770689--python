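"""Synthetic-study generators: determinism, planted truth, fixture marginals."""

import numpy as np
import pandas as pd
import pytest

from translatomics.metabolome import median_normalize, presence_calls
from translatomics.simulate import (
    SimConfig,
    draw_truth_labels,
    gen_annotations,
    gen_metabolome,
    gen_proteome,
    gen_transcripts,
    table3_fixture,
)
from translatomics.utr import scan_uorfs


class TestConfig:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="frac_regulated"):
            SimConfig(frac_regulated=1.5)

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError, match="effect_log2"):
            SimConfig(effect_log2=float("nan"))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_replicates"):
            SimConfig(n_replicates=1)

    def test_both_probability_capped_by_marginals(self):
        with pytest.raises(ValueError, match="p_both"):
            SimConfig(sp_tm_probs={"regulated": (0.1, 0.1, 0.2), "non_regulated": (0.1, 0.1, 0.05)})


class TestProteome:
    def test_same_seed_bitwise_identical(self, small_config):
        a, ta = gen_proteome(small_config)
        b, tb = gen_proteome(small_config)
        assert a.data.equals(b.data) and ta.equals(tb)

    def test_different_seed_differs(self, small_config):
        a, _ = gen_proteome(small_config)
        b, _ = gen_proteome(SimConfig(seed=small_config.seed + 1, n_proteins=200))
        assert not a.data.equals(b.data)

    def test_frac_regulated_zero_plants_nothing(self):
        _, truth = gen_proteome(SimConfig(seed=1, n_proteins=500, frac_regulated=0.0))
        assert (truth == "null").all()

    def test_label_stream_reproducible_independently(self):
        config = SimConfig(seed=7, n_proteins=2000, frac_regulated=0.05)
        _, truth = gen_proteome(config)
        redraw = draw_truth_labels(config)
        assert truth.equals(redraw)

    def test_label_swap_columns_store_reversed_orientation(self):
        config = SimConfig(seed=3, n_proteins=400, frac_regulated=0.5,
                           effect_log2=2.0, noise_sd=0.05, missing_rate=0.0,
                           up_bias=1.0)
        quant, truth = gen_proteome(config)
        swapped = [c for c, o in quant.orientation.items() if o == "swapped"]
        standard = [c for c, o in quant.orientation.items() if o == "standard"]
        assert len(swapped) == 2 and len(standard) == 2
        up = truth == "up"
        # up-regulated proteins: positive in standard, negative in swapped
        assert (quant.data.loc[up, standard].mean(axis=1) > 0).all()
        assert (quant.data.loc[up, swapped].mean(axis=1) < 0).all()

    def test_missingness_rate_close_to_configured(self):
        config = SimConfig(seed=5, n_proteins=3000, missing_rate=0.2)
        quant, _ = gen_proteome(config)
        frac = quant.data.isna().to_numpy().mean()
        se = np.sqrt(0.2 * 0.8 / quant.data.size)
        assert abs(frac - 0.2) < 3 * se


class TestTranscripts:
    def test_planted_uorfs_all_recovered_by_scanner(self, small_transcripts):
        records, planted = small_transcripts
        total = 0
        for rec in records:
            hits = set(scan_uorfs(rec))
            assert set(planted[rec.transcript_id]) <= hits
            total += len(planted[rec.transcript_id])
        assert total > 0

    def test_uorf_rate_zero_means_no_planting(self):
        config = SimConfig(seed=2, n_proteins=50,
                           uorf_rate={"regulated": 0.0, "non_regulated": 0.0})
        _, truth = gen_proteome(config)
        _, planted = gen_transcripts(config, truth)
        assert all(len(v) == 0 for v in planted.values())

    def test_gc_fraction_one_gives_pure_gc_outside_motifs(self):
        config = SimConfig(seed=2, n_proteins=30, gc_fraction=1.0,
                           uorf_rate={"regulated": 0.0, "non_regulated": 0.0})
        _, truth = gen_proteome(config)
        records, _ = gen_transcripts(config, truth)
        for rec in records:
            utr = rec.sequence[: rec.cds_start - 1]
            assert set(utr) <= {"G", "C"}

    def test_regulated_group_utrs_longer_on_average(self, small_config, small_transcripts):
        records, _ = small_transcripts
        _, truth = gen_proteome(small_config)
        lengths = {"regulated": [], "non_regulated": []}
        for rec in records:
            group = "regulated" if truth[rec.protein_id] != "null" else "non_regulated"
            lengths[group].append(rec.cds_start - 1)
        assert np.median(lengths["regulated"]) > np.median(lengths["non_regulated"])

    def test_variant_count_bounded(self, small_config, small_transcripts):
        records, _ = small_transcripts
        counts = pd.Series([r.protein_id for r in records]).value_counts()
        assert counts.max() <= small_config.variants_per_protein_max
        assert counts.min() >= 1


class TestAnnotations:
    def test_fixture_reproduces_union_38(self):
        records, groups = table3_fixture()
        regulated = [r for r in records if "regulated" in groups[r.protein_id]]
        union = sum(r.has_signal_peptide or r.has_transmembrane for r in regulated)
        assert len(regulated) == 80 and union == 38

    def test_fixture_with_incompatible_truth_rejected(self):
        truth = pd.Series(["up"] * 10, index=[f"P{i}" for i in range(10)])
        with pytest.raises(ValueError, match="1240"):
            table3_fixture(truth)

    def test_zero_probabilities_give_no_flags(self):
        config = SimConfig(seed=4, n_proteins=300,
                           sp_tm_probs={"regulated": (0.0, 0.0, 0.0),
                                        "non_regulated": (0.0, 0.0, 0.0)})
        _, truth = gen_proteome(config)
        records, _ = gen_annotations(config, truth)
        assert not any(r.has_signal_peptide or r.has_transmembrane for r in records)

    def test_stochastic_frequencies_within_three_se(self):
        config = SimConfig(seed=6, n_proteins=8000, frac_regulated=0.0)
        _, truth = gen_proteome(config)
        records, _ = gen_annotations(config, truth)
        n = len(records)
        p_sp, p_tm, p_both = config.sp_tm_probs["non_regulated"]
        for p, observed in (
            (p_sp, sum(r.has_signal_peptide for r in records)),
            (p_tm, sum(r.has_transmembrane for r in records)),
            (p_both, sum(r.has_signal_peptide and r.has_transmembrane for r in records)),
        ):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed / n - p) < 3 * se


class TestMetabolome:
    def test_same_seed_identical_table(self, small_config):
        a, _ = gen_metabolome(small_config)
        b, _ = gen_metabolome(small_config)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_planted_metabolite_called_mutant_only(self, small_config):
        peaks, truth = gen_metabolome(small_config)
        calls = {c.metabolite: c for c in presence_calls(median_normalize(peaks))}
        for m in truth["mutant_only"]:
            assert calls[m].pattern == "mutant-only"
            assert calls[m].consistent_across_timepoints

    def test_no_planting_gives_symmetric_presence(self):
        config = SimConfig(seed=9, n_proteins=20)
        peaks, truth = gen_metabolome(config)
        calls = {c.metabolite: c for c in presence_calls(median_normalize(peaks))}
        for c in calls.values():
            if c.metabolite not in truth["mutant_only"]:
                assert c.pattern == "both"
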