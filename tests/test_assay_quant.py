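import numpy as np
import pandas as pd
import pytest
from scipy import stats

import denovolib as dl
from denovolib.assay_quant import ReferenceIndex
from denovolib.synthetic_data import READ_PAD3, READ_PAD5

from toy_assay import TOY_EXPECTED, TOY_REFS, TOY_SCHEME, toy_reads


class TestDemultiplex:
    def test_exact_pair_assigned(self):
        reads = toy_reads()[:1]
        assigned, unassigned = dl.demultiplex(reads, TOY_SCHEME)
        assert len(assigned["pre1"]) == 1 and not unassigned

    def test_distance_two_unassigned(self):
        r = toy_reads()[0]
        seq = "TT" + r[1][2:]  # 2 mismatches in the 5' barcode
        assigned, unassigned = dl.demultiplex([(r[0], seq, r[2])], TOY_SCHEME)
        assert len(unassigned) == 1

    def test_ambiguous_tie_unassigned(self):
        scheme = dl.BarcodeScheme(
            barcodes={"s1": ("AAAAAAAA", "CCCCCCCC"), "s2": ("AAAAAATT", "CCCCCCGG")}
        )
        # one mismatch from each sample's bc5, identical situation at bc3
        read = ("r", "AAAAAAAT" + "ACGT" * 3 + "CCCCCCCG", "I" * 28)
        assigned, unassigned = dl.demultiplex([read], scheme)
        assert len(unassigned) == 1

    def test_duplicate_barcode_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            dl.BarcodeScheme(
                barcodes={"a": ("AAAAAAAA", "CCCCCCCC"), "b": ("AAAAAAAA", "CCCCCCCC")}
            )


class TestAssignRead:
    def test_exact_match(self):
        assert dl.assign_read(TOY_REFS["v01"], TOY_REFS) == "v01"

    def test_single_substitution(self):
        read = "ATGCAA" + TOY_REFS["v01"][6:]
        assert dl.assign_read(read, TOY_REFS, max_edit=2) == "v01"

    def test_equidistant_ambiguous(self):
        refs = {"u1": "ATGCCTTCC", "u2": "ATGCCGGCC"}
        read = "ATGCCTGCC"  # distance 1 from each
        assert dl.assign_read(read, refs, max_edit=2) == "ambiguous"

    def test_too_far_unmapped(self):
        assert dl.assign_read("ATGCACCACCAC", TOY_REFS, max_edit=2) == "unmapped"

    def test_duplicate_references_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReferenceIndex({"a": "ATGAAA", "b": "ATGAAA"})


class TestRpmDetection:
    def test_rpm_arithmetic(self):
        counts = pd.DataFrame({"s": [5, 15]}, index=["v1", "v2"])
        rpm = dl.rpm_normalize(counts)
        assert list(rpm["s"]) == [250_000.0, 750_000.0]
        assert rpm["s"].sum() == pytest.approx(1e6)

    def test_zero_count_zero_rpm(self):
        counts = pd.DataFrame({"s": [0, 10]}, index=["v1", "v2"])
        assert dl.rpm_normalize(counts)["s"]["v1"] == 0.0

    def test_zero_depth_sample_flagged(self):
        counts = pd.DataFrame({"s": [0, 0], "t": [1, 1]}, index=["v1", "v2"])
        rpm = dl.rpm_normalize(counts)
        assert rpm.attrs["excluded_samples"] == ["s"]
        assert list(rpm.columns) == ["t"]

    def test_threshold_inclusive(self):
        col = np.array([100.0, 99.999, 500.0, 0.0])
        assert dl.detected_fraction(col, 4) == pytest.approx(0.5)

    def test_all_detected(self):
        assert dl.detected_fraction(np.full(1800, 200.0), 1800) == 1.0

    def test_no_reads(self):
        assert dl.detected_fraction(np.zeros(10), 10) == 0.0

    def test_monotone_in_threshold(self, rng):
        col = rng.lognormal(5, 2, 500)
        fracs = [dl.detected_fraction(col, 500, t) for t in (10, 50, 100, 500, 1000)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestGrubbs:
    def test_constant_values_untouched(self):
        vals, excl = dl.grubbs_exclude([1, 1, 1, 1, 1])
        assert vals == [1, 1, 1, 1, 1] and excl == []

    def test_obvious_outlier_excluded(self):
        """G = 1.789 for the 5.0 point vs the published n=5, alpha=0.05
        two-sided Grubbs critical value 1.715."""
        data = [0.7, 0.71, 0.69, 0.70, 5.0]
        arr = np.array(data)
        g = abs(arr - arr.mean()).max() / arr.std(ddof=1)
        assert g == pytest.approx(1.789, abs=5e-3)
        assert g > 1.715
        vals, excl = dl.grubbs_exclude(data, alpha=0.05)
        assert excl == [4] and 5.0 not in vals

    def test_exclusion_cap(self):
        data = [0.1, 0.2, 0.15, 50.0, 60.0]
        _, excl = dl.grubbs_exclude(data, max_excluded=1)
        assert len(excl) <= 1

    def test_small_sample_returned_unchanged(self):
        vals, excl = dl.grubbs_exclude([1.0, 9.0])
        assert vals == [1.0, 9.0] and excl == []


class TestSurvivalEstimate:
    def test_ratio_arithmetic(self):
        est = dl.survival_estimate([0.8, 0.75], [0.6, 0.6])
        assert sorted(est.ratios.values()) == pytest.approx([0.75, 0.8])
        assert est.mean == pytest.approx(0.775)

    def test_no_selection_gives_unity(self):
        est = dl.survival_estimate([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert est.mean == 1.0 and est.sd == 0.0
        assert est.ci95 == (1.0, 1.0)

    def test_zero_pre_pair_dropped(self):
        est = dl.survival_estimate([0.0, 0.5, 0.5], [0.1, 0.25, 0.25])
        assert len(est.ratios) == 2

    def test_ci_covers_truth(self, rng):
        """t-based 95% CI over 9 replicate ratios covers the true survival
        of 0.7 in at least 90 of 100 simulated assays."""
        hits = 0
        for _ in range(100):
            pre = 0.75 + rng.normal(0, 0.02, 9)
            post = pre * (0.7 + rng.normal(0, 0.05, 9))
            est = dl.survival_estimate(pre, post)
            hits += est.ci95[0] <= 0.7 <= est.ci95[1]
        assert hits >= 90


class TestWelch:
    def test_identical_degenerate_groups(self):
        res = dl.one_tailed_welch([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res["t"] == 0.0 and res["p"] == 0.5

    def test_clear_separation(self):
        res = dl.one_tailed_welch([11, 12, 13], [1, 2, 3], alternative="greater")
        assert res["p"] < 1e-3

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 9)
        res = dl.one_tailed_welch(a, b, alternative="less")
        ref = stats.ttest_ind(a, b, equal_var=False, alternative="less")
        assert res["t"] == pytest.approx(float(ref.statistic))
        assert res["p"] == pytest.approx(float(ref.pvalue))


class TestToyPipeline:
    """Full chain on hand-written reads: every number matches hand
    computation exactly."""

    @pytest.fixture(scope="class")
    def chain(self):
        assigned, unassigned = dl.demultiplex(toy_reads(), TOY_SCHEME)
        counts = dl.count_reads(assigned, TOY_REFS, pad5=READ_PAD5, pad3=READ_PAD3)
        return assigned, unassigned, counts

    def test_unassigned_tally(self, chain):
        _, unassigned, _ = chain
        assert len(unassigned) == TOY_EXPECTED["n_unassigned"]

    def test_counts_exact(self, chain):
        _, _, counts = chain
        for sample, expected in TOY_EXPECTED["counts"].items():
            col = counts[sample]
            assert {v: int(c) for v, c in col.items() if c} == expected

    def test_rpm_exact(self, chain):
        _, _, counts = chain
        rpm = dl.rpm_normalize(counts)
        for vid, val in TOY_EXPECTED["rpm_pre1"].items():
            assert rpm["pre1"][vid] == val

    def test_detected_fractions_exact(self, chain):
        _, _, counts = chain
        rpm = dl.rpm_normalize(counts)
        for sample, frac in TOY_EXPECTED["detected"].items():
            assert dl.detected_fraction(rpm[sample], 10) == frac

    def test_survival_exact(self, chain):
        _, _, counts = chain
        est = dl.survival_from_counts(
            counts[["pre1", "pre2"]], counts[["post1", "post2"]], n_designed=10
        )
        assert est.ratios == TOY_EXPECTED["ratios"]
        assert est.mean == TOY_EXPECTED["mean_survival"]

    def test_depth_rescaling_invariance(self, chain):
        _, _, counts = chain
        est1 = dl.survival_from_counts(
            counts[["pre1", "pre2"]], counts[["post1", "post2"]], n_designed=10
        )
        est2 = dl.survival_from_counts(
            counts[["pre1", "pre2"]] * 3, counts[["post1", "post2"]] * 3, n_designed=10
        )
        assert est1.mean == est2.mean and est1.ratios == est2.ratios
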