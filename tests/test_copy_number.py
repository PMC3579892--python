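import numpy as np
import pandas as pd
import pytest

from subtypeforge import (
    CNEvent,
    CopyNumberCohort,
    DataError,
    GeneRegion,
    Segment,
    SegmentedProfile,
    SimConfig,
    call_gene_event,
    chromosomal_instability_index,
    cyclic_shift_peak_test,
    gene_level_copy_number,
    impute_missing_markers,
    peak_confidence_interval,
    peel_and_repeat,
    region_subtype_association,
    segment_profile,
    simulate_copy_number_cohort,
    simulate_subtyped_expression,
    smooth_and_center_profiles,
)


def make_cohort(values, positions=None, chroms=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim == 2 and values.shape[1] == 1:
        values = values
    m = values.shape[0]
    positions = positions if positions is not None else list(range(1, m + 1))
    chroms = chroms or ["chr1"] * m
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    ids = [f"m{i}" for i in range(m)]
    markers = pd.DataFrame({"chrom": chroms, "pos": positions}, index=ids)
    arm = pd.Series([f"{c}q" for c in chroms], index=ids)
    return CopyNumberCohort(markers=markers,
                            values=pd.DataFrame(values, index=ids,
                                                columns=samples),
                            arm_map=arm)


class TestImputation:
    def test_nearest_neighbor_with_upstream_tie(self):
        cohort = make_cohort(np.array([[np.nan, 0.3, np.nan, np.nan, 0.9]]).T)
        out = impute_missing_markers(cohort)
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [0.3, 0.3, 0.3, 0.9, 0.9])

    def test_no_missing_is_identity(self):
        cohort = make_cohort(np.array([[0.1, 0.2, 0.3]]).T)
        out = impute_missing_markers(cohort)
        pd.testing.assert_frame_equal(out.values, cohort.values)

    def test_leading_missing_run_filled_forward(self):
        cohort = make_cohort(np.array([[np.nan, np.nan, 0.5, 0.7]]).T)
        out = impute_missing_markers(cohort)
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [0.5, 0.5, 0.5, 0.7])

    def test_fully_missing_chromosome_rejected(self):
        cohort = make_cohort(np.array([[np.nan, np.nan]]).T)
        with pytest.raises(DataError, match="chr1"):
            impute_missing_markers(cohort)


class TestSmoothing:
    def test_flat_profile_centers_to_zero(self):
        cohort = make_cohort(np.full((20, 1), 0.2))
        out = smooth_and_center_profiles(cohort)
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)

    def test_single_spike_shrunk(self):
        vals = np.zeros((30, 1))
        vals[15, 0] = 4.0
        out = smooth_and_center_profiles(make_cohort(vals))
        assert abs(out.values.iloc[15, 0]) < 1e-12

    def test_sample_medians_exactly_zero(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort(rng.normal(0, 0.3, size=(101, 4)))
        out = smooth_and_center_profiles(cohort)
        np.testing.assert_allclose(out.values.median(axis=0), 0.0, atol=1e-15)


class TestSegmentation:
    def test_constant_profile_single_segment(self):
        cohort = make_cohort(np.full((30, 1), 0.1))
        prof = segment_profile(cohort, "s0")
        assert len(prof.segments) == 1
        assert prof.segments[0].n_markers == 30

    def test_segments_partition_markers(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.2, size=(120, 1))
        vals[40:80] += 1.0
        cohort = make_cohort(vals)
        prof = segment_profile(cohort, "s0")
        assert sum(s.n_markers for s in prof.segments) == 120
        assert prof.marker_values.notna().all()

    def test_breakpoint_recovery(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            vals = rng.normal(0, 0.1, size=(200, 1))
            vals[100:] += 0.8
            prof = segment_profile(make_cohort(vals), "s0")
            breaks = [s.start for s in prof.segments[1:]]
            # positions are 1-based integers 1..200 -> marker index = pos - 1
            if any(abs(b - 101) <= 3 for b in breaks):
                hits += 1
        assert hits >= 0.95 * n_rep


class TestCyclicShiftTest:
    def test_all_zero_cohort_p_one(self):
        cohort = make_cohort(np.zeros((50, 6)))
        call = cyclic_shift_peak_test(cohort, "gain", n_perm=50, seed=0)
        assert call.statistic == 0.0
        assert call.p_value == 1.0

    def test_planted_gain_detected(self):
        cfg = SimConfig(n_samples=60, n_genes=40, seed=77,
                        n_informative_genes_per_subtype=5, cn_noise_sd=0.2,
                        cn_events=(CNEvent("gain", "chr3", 30_000_000,
                                           60_000_000, 0.6, 0.4, None),))
        _, labels = simulate_subtyped_expression(cfg)
        cohort, truth = simulate_copy_number_cohort(cfg, labels)
        sm = smooth_and_center_profiles(impute_missing_markers(cohort))
        call = cyclic_shift_peak_test(sm, "gain", n_perm=250, seed=0)
        assert call.p_value <= 0.05
        assert call.peak_marker in truth[0]["markers"]

    def test_statistic_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 8))
        a = cyclic_shift_peak_test(make_cohort(vals), "gain", n_perm=20, seed=1)
        b = cyclic_shift_peak_test(make_cohort(vals[:, ::-1]), "gain",
                                   n_perm=20, seed=1)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.peak_marker == b.peak_marker

    def test_loss_direction_finds_minimum(self):
        vals = np.zeros((30, 4))
        vals[10, :] = -1.0
        call = cyclic_shift_peak_test(make_cohort(vals), "loss", n_perm=50,
                                      seed=0)
        assert call.peak_marker == "m10"


class TestPeakConfidenceInterval:
    def test_single_marker_chromosome(self):
        cohort = make_cohort(np.array([[0.5, 0.4, 0.6]]))  # 1 marker, 3 samples
        left, right = peak_confidence_interval(cohort, "gain", n_boot=50,
                                               seed=0)
        assert left == right == "m0"

    def test_interval_brackets_peak(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.2, size=(80, 10))
        vals[30:40] += 0.8
        cohort = make_cohort(vals)
        left, right = peak_confidence_interval(cohort, "gain", n_boot=200,
                                               seed=0)
        peak = cyclic_shift_peak_test(cohort, "gain", n_perm=10, seed=0)
        ids = list(cohort.values.index)
        assert ids.index(left) <= ids.index(peak.peak_marker) <= ids.index(right)


class TestPeeling:
    def test_two_events_recovered_in_two_rounds(self):
        cfg = SimConfig(
            n_samples=60, n_genes=40, seed=31, cn_noise_sd=0.2,
            n_informative_genes_per_subtype=5,
            cn_events=(
                CNEvent("gain", "chr2", 30_000_000, 60_000_000, 0.7, 0.4, None),
                CNEvent("gain", "chr6", 90_000_000, 120_000_000, 0.7, 0.4, None),
            ))
        _, labels = simulate_subtyped_expression(cfg)
        cohort, truth = simulate_copy_number_cohort(cfg, labels)
        sm = smooth_and_center_profiles(impute_missing_markers(cohort))
        peaks = peel_and_repeat(sm, "gain", n_peaks=3, n_perm=100, seed=0,
                                with_ci=False)
        assert len(peaks) >= 2
        planted = [set(t["markers"]) for t in truth]
        found = {peaks[0].peak_marker, peaks[1].peak_marker}
        assert any(p in planted[0] for p in found)
        assert any(p in planted[1] for p in found)
        assert all(p.p_value <= 0.05 for p in peaks)

    def test_noise_cohort_stops_early(self):
        rng = np.random.default_rng(9)
        cohort = make_cohort(rng.normal(0, 0.2, size=(200, 20)))
        sm = smooth_and_center_profiles(cohort)
        peaks = peel_and_repeat(sm, "gain", n_peaks=5, n_perm=100, seed=0,
                                with_ci=False)
        assert len(peaks) <= 1


class TestGeneLevel:
    def _profile(self, seg_vals, positions=None):
        m = len(seg_vals)
        positions = positions or list(range(10, 10 * m + 1, 10))
        ids = [f"m{i}" for i in range(m)]
        markers = pd.DataFrame({"chrom": ["chr1"] * m, "pos": positions},
                               index=ids)
        prof = SegmentedProfile(
            sample_id="s0",
            segments=[Segment("chr1", positions[0], positions[-1] + 1, m, 0.0)],
            marker_values=pd.Series(seg_vals, index=ids, dtype=float))
        return prof, markers

    def test_gene_inside_one_segment(self):
        prof, markers = self._profile([0.42] * 5)
        gene = GeneRegion("CCND1", "chr1", 15, 45)
        assert gene_level_copy_number(prof, markers, gene,
                                      n_flank=0) == pytest.approx(0.42)

    def test_mean_without_flanks(self):
        prof, markers = self._profile([0.5, 0.5, 0.1])
        gene = GeneRegion("EGFR", "chr1", 5, 35)
        value = gene_level_copy_number(prof, markers, gene, n_flank=0)
        assert value == pytest.approx(1.1 / 3, abs=5e-5)

    def test_gene_between_markers_uses_flanks(self):
        prof, markers = self._profile([0.2, 0.6], positions=[10, 100])
        gene = GeneRegion("CDKN2A", "chr1", 40, 60)
        assert gene_level_copy_number(prof, markers, gene) == pytest.approx(0.4)

    def test_distant_gene_rejected(self):
        prof, markers = self._profile([0.2, 0.6], positions=[10, 100])
        gene = GeneRegion("FAR", "chr1", 5_000_000, 5_000_100)
        with pytest.raises(DataError, match="FAR"):
            gene_level_copy_number(prof, markers, gene)


class TestGeneEventCalls:
    @pytest.mark.parametrize("value,expected", [
        (0.42, "gain"),
        (-0.42, "loss"),
        (0.35, "neutral"),
        (-0.35, "neutral"),
        (0.0, "neutral"),
    ])
    def test_threshold_calls(self, value, expected):
        assert call_gene_event(value) == expected


class TestChromosomalInstability:
    def test_zero_profile(self):
        vals = pd.Series([0.0] * 6, index=[f"m{i}" for i in range(6)])
        arms = pd.Series(["1p"] * 3 + ["1q"] * 3, index=vals.index)
        assert chromosomal_instability_index(vals, arms) == 0.0

    def test_two_arm_example(self):
        vals = pd.Series([0.1, -0.1, 0.3, -0.2, -0.4, -0.6],
                         index=[f"m{i}" for i in range(6)])
        arms = pd.Series(["1p"] * 3 + ["1q"] * 3, index=vals.index)
        assert chromosomal_instability_index(vals, arms) == pytest.approx(0.25)

    def test_homogeneity_and_sign_invariance(self):
        rng = np.random.default_rng(6)
        vals = pd.Series(rng.normal(size=40), index=[f"m{i}" for i in range(40)])
        arms = pd.Series(["1p"] * 10 + ["1q"] * 10 + ["2p"] * 10 + ["2q"] * 10,
                         index=vals.index)
        base = chromosomal_instability_index(vals, arms)
        assert chromosomal_instability_index(3 * vals, arms) == pytest.approx(3 * base)
        flipped = vals.copy()
        flipped[arms == "1q"] *= -1
        assert chromosomal_instability_index(flipped, arms) == pytest.approx(base)


class TestRegionAssociation:
    def test_subtype_specific_gain_detected(self):
        cfg = SimConfig(n_samples=80, n_genes=40, seed=13, cn_noise_sd=0.2,
                        n_informative_genes_per_subtype=5,
                        cn_events=(CNEvent("gain", "chr4", 30_000_000,
                                           60_000_000, 0.6, 0.9, (1,)),))
        _, labels = simulate_subtyped_expression(cfg)
        cohort, truth = simulate_copy_number_cohort(cfg, labels)
        sm = smooth_and_center_profiles(impute_missing_markers(cohort))
        covered = truth[0]["markers"]
        res = region_subtype_association(sm, labels,
                                         (covered[0], covered[-1]))
        assert res["p_value"] <= 0.01

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(2)
        cohort = make_cohort(rng.normal(size=(30, 12)))
        labels = pd.Series([0, 1, 2] * 4, index=cohort.values.columns)
        res = region_subtype_association(cohort, labels, ("m5", "m10"),
                                         n_tests=10)
        assert res["p_adjusted"] == pytest.approx(min(1.0, res["p_value"] * 10))

    def test_single_subtype_rejected(self):
        cohort = make_cohort(np.zeros((10, 4)))
        labels = pd.Series([1] * 4, index=cohort.values.columns)
        with pytest.raises(DataError):
            region_subtype_association(cohort, labels, ("m0", "m5"))
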