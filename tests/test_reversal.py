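"""Binning of perturbation ratios and treated-response classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revtraj import (
    ClassificationConfig,
    GeneMismatchError,
    assign_bins,
    classify_t20_response,
    summarize_bins,
    summarize_strata,
)

from conftest import make_ratio_table


def brute_force_response(r1, rT, cfg):
    """Straight-line re-statement of the threshold rules, one gene at a time."""
    out = []
    for v1, vT in zip(r1, rT):
        if v1 < cfg.down_stratum_max_ratio:
            stratum = "down"
        elif v1 > cfg.up_stratum_min_ratio:
            stratum = "up"
        else:
            stratum = "neither"
        if vT > cfg.ns_upper:
            category = "increased"
        elif vT < cfg.ns_lower:
            category = "decreased"
        else:
            category = "not_significant"
        if stratum == "neither":
            interp = "not_applicable"
        elif category == "not_significant":
            interp = "unaffected"
        elif stratum == "down" and category == "increased":
            interp = "reversed"
        elif stratum == "down" and category == "decreased":
            interp = "consistent"
        elif stratum == "up" and category == "decreased":
            interp = "reversed"
        else:
            interp = "consistent"
        out.append((stratum, category, interp))
    return out


class TestAssignBins:
    def test_zero_log2_lands_in_first_bin_containing_zero(self, cc):
        # 14 bins of width 0.5 over [-3.5, 3.5): zero is the lower edge of bin 7
        rt = make_ratio_table([1.0])
        assert assign_bins(rt, cc)[0] == 7

    @pytest.mark.parametrize("ratio, bin_", [(2.0 ** -10, 0), (2.0 ** 10, 13)])
    def test_out_of_range_values_fall_in_catch_all_bins(self, cc, ratio, bin_):
        rt = make_ratio_table([ratio])
        assert assign_bins(rt, cc)[0] == bin_

    def test_counts_match_numpy_histogram_oracle(self, cc):
        rng = np.random.default_rng(5)
        log2 = rng.uniform(-3.5, 3.5 - 1e-9, 1000)
        rt = make_ratio_table(2.0 ** log2)
        bins = assign_bins(rt, cc)
        ours = np.bincount(bins, minlength=14)
        expected, _ = np.histogram(log2, bins=np.linspace(-3.5, 3.5, 15))
        np.testing.assert_array_equal(ours, expected)

    def test_every_gene_binned_exactly_once(self, cc):
        rng = np.random.default_rng(8)
        rt = make_ratio_table(2.0 ** rng.normal(0, 3, 500))
        bins = assign_bins(rt, cc)
        assert bins.shape == (500,)
        assert np.all((bins >= 0) & (bins < cc.n_bins))


class TestSummarizeBins:
    def test_unit_rT_gives_zero_means(self, cc):
        rng = np.random.default_rng(2)
        n = 200
        r1 = make_ratio_table(2.0 ** rng.uniform(-3, 3, n))
        rT = make_ratio_table(np.ones(n))
        for b in summarize_bins(r1, rT, cc):
            if b.gene_count:
                assert b.mean_log2_rT == pytest.approx(0.0)

    def test_singleton_bin_has_no_standard_error(self, cc):
        r1 = make_ratio_table([1.0])  # bin 7 only
        rT = make_ratio_table([4.0])
        bins = summarize_bins(r1, rT, cc)
        b = bins[7]
        assert b.gene_count == 1
        assert b.mean_log2_rT == pytest.approx(2.0)
        assert b.standard_error_log2_rT is None
        assert all(x.gene_count == 0 and x.mean_log2_rT is None for i, x in enumerate(bins) if i != 7)

    def test_gene_counts_sum_to_total(self, cc):
        rng = np.random.default_rng(13)
        n = 777
        r1 = make_ratio_table(2.0 ** rng.normal(0, 2, n))
        rT = make_ratio_table(2.0 ** rng.normal(0, 1, n))
        assert sum(b.gene_count for b in summarize_bins(r1, rT, cc)) == n

    def test_mismatched_tables_rejected(self, cc):
        with pytest.raises(GeneMismatchError):
            summarize_bins(make_ratio_table([1.0, 2.0]), make_ratio_table([1.0]), cc)


class TestClassifyResponse:
    def test_strong_down_gene_rescued_by_treatment_is_reversed(self, cc):
        labels = classify_t20_response(
            make_ratio_table([0.4]), make_ratio_table([1.8]), cc
        )
        (l,) = labels
        assert (l.baseline_stratum, l.t20_category, l.interpretation) == (
            "down",
            "increased",
            "reversed",
        )

    def test_unchanged_gene_is_not_applicable(self, cc):
        (l,) = classify_t20_response(make_ratio_table([1.0]), make_ratio_table([1.0]), cc)
        assert l.baseline_stratum == "neither"
        assert l.interpretation == "not_applicable"

    def test_band_edges_inclusive(self, cc):
        r1 = make_ratio_table([0.4, 0.4])
        rT = make_ratio_table([0.67, 1.50])
        for l in classify_t20_response(r1, rT, cc):
            assert l.t20_category == "not_significant"
            assert l.interpretation == "unaffected"

    def test_matches_brute_force_oracle_on_random_genes(self, cc):
        rng = np.random.default_rng(99)
        n = 10_000
        v1 = 2.0 ** rng.uniform(-4, 4, n)
        vT = 2.0 ** rng.uniform(-3, 3, n)
        labels = classify_t20_response(make_ratio_table(v1), make_ratio_table(vT), cc)
        expected = brute_force_response(v1, vT, cc)
        got = [(l.baseline_stratum, l.t20_category, l.interpretation) for l in labels]
        assert got == expected

    def test_partition_completeness(self, cc):
        rng = np.random.default_rng(17)
        n = 3000
        labels = classify_t20_response(
            make_ratio_table(2.0 ** rng.normal(0, 2, n)),
            make_ratio_table(2.0 ** rng.normal(0, 1, n)),
            cc,
        )
        report = summarize_strata(labels)
        assert (
            report["down"]["total"] + report["up"]["total"] + report["neither"]["total"]
            == n
        )
        for stratum in ("down", "up"):
            assert sum(report[stratum]["counts"].values()) == report[stratum]["total"]

    @settings(derandomize=True, max_examples=40)
    @given(
        ratio=st.floats(0.01, 100.0),
        widen=st.floats(0.01, 5.0),
    )
    def test_widening_ns_band_never_creates_increased(self, ratio, widen):
        """Raising ns_upper can only move genes out of 'increased', never into it."""
        narrow = ClassificationConfig()
        wide = ClassificationConfig(ns_upper=narrow.ns_upper + widen)
        r1 = make_ratio_table([0.3])
        rT = make_ratio_table([ratio])
        cat_narrow = classify_t20_response(r1, rT, narrow)[0].t20_category
        cat_wide = classify_t20_response(r1, rT, wide)[0].t20_category
        assert not (cat_narrow == "not_significant" and cat_wide == "increased")

    @settings(derandomize=True, max_examples=40)
    @given(ratio=st.floats(0.01, 100.0), shift=st.floats(0.0, 0.4))
    def test_raising_down_threshold_never_shrinks_down_stratum(self, ratio, shift):
        small = ClassificationConfig(down_stratum_max_ratio=0.5)
        large = ClassificationConfig(down_stratum_max_ratio=0.5 + shift)
        r1 = make_ratio_table([ratio])
        rT = make_ratio_table([1.0])
        in_small = classify_t20_response(r1, rT, small)[0].baseline_stratum == "down"
        in_large = classify_t20_response(r1, rT, large)[0].baseline_stratum == "down"
        assert in_large or not in_small


def make_printed_count_labels(cc):
    """Ratio pairs realizing the published per-stratum outcome counts."""
    v1, vT = [], []
    for n, rt in [(509, 1.0), (514, 2.0), (51, 0.5)]:  # down stratum
        v1 += [0.4] * n
        vT += [rt] * n
    for n, rt in [(614, 1.0), (339, 0.5), (181, 2.0)]:  # up stratum
        v1 += [3.0] * n
        vT += [rt] * n
    return classify_t20_response(make_ratio_table(v1), make_ratio_table(vT), cc)


class TestSummarizeStrata:
    def test_reproduces_published_stratum_totals(self, cc):
        report = summarize_strata(make_printed_count_labels(cc))
        assert report["down"]["total"] == 1074
        assert report["down"]["counts"] == {
            "unaffected": 509,
            "reversed": 514,
            "consistent": 51,
        }
        assert report["up"]["total"] == 1134
        assert report["up"]["counts"] == {
            "unaffected": 614,
            "reversed": 339,
            "consistent": 181,
        }

    def test_percentages_relative_to_stratum_total(self, cc):
        report = summarize_strata(make_printed_count_labels(cc))
        assert report["down"]["percentages"]["reversed"] == pytest.approx(47.9)
        assert report["up"]["percentages"]["unaffected"] == pytest.approx(54.1)

    def test_empty_labels_give_zero_report(self):
        report = summarize_strata([])
        assert report["total_genes"] == 0
        assert report["down"]["total"] == 0
        assert report["up"]["counts"] == {
            "unaffected": 0,
            "reversed": 0,
            "consistent": 0,
        }
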