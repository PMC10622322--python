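"""Peak matching, angular similarity, RT calibration and target-decoy FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from haplopept.psm_qc import (
    MATCHED,
    MISSING_PREDICTION,
    UNANNOTATED,
    UNMATCHED,
    MatchedPeakVectors,
    Spectrum,
    angular_similarity,
    annotate_mirror,
    match_peaks,
    rt_deviation,
    scale_observed,
    target_decoy_qvalues,
)

from oracles import brute_force_qvalues


def spec(mz, intensity, **kw):
    return Spectrum(mz=np.asarray(mz, float), intensity=np.asarray(intensity, float), **kw)


class TestSpectrumValidation:
    def test_mz_must_increase(self):
        with pytest.raises(ValueError):
            spec([100.0, 100.0], [1.0, 1.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            spec([100.0], [-1.0])


class TestMatchPeaks:
    def test_within_tolerance_matches(self):
        v, ann = match_peaks(spec([500.0000], [1.0]), spec([500.0025], [2.0]))
        assert v.n == 1  # 5 ppm
        assert ann.observed == (MATCHED,)

    def test_beyond_tolerance_unmatched(self):
        v, ann = match_peaks(spec([500.0100], [1.0]), spec([500.0000], [2.0]))
        assert v.n == 0  # 20 ppm
        assert ann.observed == (UNMATCHED,)
        assert ann.predicted == (UNMATCHED,)

    def test_equidistant_tie_goes_to_lower_predicted_mz(self):
        # exact ppm tie (power-of-two values, wide tolerance): the
        # observed peak at 384 is 0.5e6 ppm from both 256 and 768
        observed = spec([384.0], [1.0])
        predicted = spec([256.0, 768.0], [1.0, 1.0])
        _, ann = match_peaks(observed, predicted, tolerance_ppm=600000.0)
        assert ann.predicted == (MATCHED, UNMATCHED)

    def test_one_to_one_assignment_by_smallest_ppm(self):
        observed = spec([500.0000, 500.0030], [1.0, 1.0])
        predicted = spec([500.0010], [1.0])
        v, ann = match_peaks(observed, predicted)
        assert v.n == 1
        assert ann.observed == (MATCHED, UNMATCHED)

    def test_missing_prediction_category_excluded_from_vectors(self):
        observed = spec([400.0, 500.0], [1.0, 2.0])
        predicted = spec([400.0, 500.0], [np.nan, 3.0])
        v, ann = match_peaks(observed, predicted)
        assert ann.observed == (MISSING_PREDICTION, MATCHED)
        assert v.n == 1
        assert v.M.tolist() == [2.0] and v.P.tolist() == [3.0]

    def test_empty_observed_gives_empty_result(self):
        v, ann = match_peaks(spec([], []), spec([500.0], [1.0]))
        assert v.n == 0
        assert ann.predicted == (UNMATCHED,)


class TestScaleObserved:
    def test_median_matching_factor(self):
        out = scale_observed(
            spec([1.0, 2.0, 3.0], [2.0, 4.0, 6.0]),
            spec([1.0, 2.0, 3.0], [8.0, 8.0, 8.0]),
        )
        assert out.intensity.tolist() == [4.0, 8.0, 12.0]

    def test_equal_medians_unchanged(self):
        out = scale_observed(
            spec([1.0], [5.0]), spec([1.0, 2.0], [5.0, 5.0])
        )
        assert out.intensity.tolist() == [5.0]

    def test_all_zero_observed_errors(self):
        with pytest.raises(ValueError):
            scale_observed(
                spec([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]), spec([1.0], [4.0])
            )

    def test_zero_median_falls_back_to_mean(self):
        out = scale_observed(
            spec([1.0, 2.0, 3.0], [0.0, 0.0, 3.0]), spec([1.0], [4.0])
        )
        # mean 1.0 -> factor 4
        assert out.intensity.tolist() == [0.0, 0.0, 12.0]


class TestAngularSimilarity:
    def test_identical_vectors_give_one(self):
        v = MatchedPeakVectors(np.array([3.0, 1.0, 2.0]), np.array([3.0, 1.0, 2.0]))
        assert angular_similarity(v) == 1.0

    def test_orthogonal_vectors_give_half(self):
        v = MatchedPeakVectors(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert angular_similarity(v) == pytest.approx(0.5)

    def test_cosine_sqrt2_over_2_gives_three_quarters(self):
        v = MatchedPeakVectors(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert angular_similarity(v) == pytest.approx(0.75)

    def test_empty_vectors_are_missing_not_zero(self):
        assert np.isnan(angular_similarity(MatchedPeakVectors(np.array([]), np.array([]))))

    def test_all_zero_vector_undefined(self):
        with pytest.raises(ValueError):
            angular_similarity(
                MatchedPeakVectors(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
            )

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(0.001, 1e3), min_size=1, max_size=20),
        st.data(),
    )
    def test_range_symmetry_and_scale_invariance(self, m, data):
        p = data.draw(
            st.lists(st.floats(0.001, 1e3), min_size=len(m), max_size=len(m))
        )
        c = data.draw(st.floats(1e-3, 1e3))
        m, p = np.array(m), np.array(p)
        a = angular_similarity(MatchedPeakVectors(m, p))
        assert 0.5 <= a <= 1.0
        assert angular_similarity(MatchedPeakVectors(p, m)) == pytest.approx(a, abs=1e-12)
        assert angular_similarity(MatchedPeakVectors(c * m, p)) == pytest.approx(a, abs=1e-9)

    def test_equals_one_iff_proportional(self):
        m = np.array([1.0, 2.0, 3.0])
        assert angular_similarity(MatchedPeakVectors(m, 7.5 * m)) == 1.0
        assert angular_similarity(MatchedPeakVectors(m, m + np.array([0, 0, 1e-3]))) < 1.0


class TestRtDeviation:
    def test_identical_series_give_zero(self):
        rt = np.array([10.0, 20.0, 30.0, 40.0])
        dev = rt_deviation(rt, rt, np.ones(4, bool))
        assert np.allclose(dev, 0.0)

    def test_hand_computed_z_scores(self):
        # calibration mean 40, sd 10 in both series
        observed = np.array([30.0, 50.0, 50.0])
        predicted = np.array([30.0, 50.0, 45.0])
        mask = np.array([True, True, False])
        dev = rt_deviation(observed, predicted, mask)
        sd = np.std([30.0, 50.0], ddof=1)
        assert dev[2] == pytest.approx(abs(10.0 / sd - 5.0 / sd))
        assert dev[:2] == pytest.approx([0.0, 0.0])

    def test_single_psm_calibration_rejected(self):
        with pytest.raises(ValueError):
            rt_deviation(
                np.array([1.0, 2.0]),
                np.array([1.0, 2.0]),
                np.array([True, False]),
            )

    def test_zero_variance_names_series(self):
        with pytest.raises(ValueError, match="predicted"):
            rt_deviation(
                np.array([1.0, 2.0]),
                np.array([5.0, 5.0]),
                np.array([True, True]),
            )


class TestTargetDecoyQvalues:
    def _frame(self, scores, labels):
        return pd.DataFrame({"score": scores, "label": labels})

    def test_hand_computed_running_minimum(self):
        df = self._frame([10.0, 9.0, 8.0, 8.5], ["target"] * 3 + ["decoy"])
        scored, confident = target_decoy_qvalues(df)
        by_score = scored.set_index("score")["q_value"]
        assert by_score[10.0] == 0.0
        assert by_score[9.0] == 0.0
        assert by_score[8.0] == pytest.approx(1 / 3)
        assert sorted(confident["score"]) == [9.0, 10.0]

    def test_no_decoys_gives_zero_qvalues(self):
        scored, _ = target_decoy_qvalues(
            self._frame([3.0, 2.0, 1.0], ["target"] * 3)
        )
        assert (scored["q_value"] == 0.0).all()

    def test_decoys_outscoring_targets_give_qvalue_one(self):
        scored, confident = target_decoy_qvalues(
            self._frame([5.0, 4.0, 3.0, 2.0], ["decoy", "decoy", "target", "target"])
        )
        targets = scored[scored["label"] == "target"]
        assert (targets["q_value"] == 1.0).all()
        assert confident.empty

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            target_decoy_qvalues(self._frame([1.0], ["decoy"]))

    def test_contaminant_matches_removed_from_confident_subset(self):
        df = pd.DataFrame(
            {
                "score": [10.0, 9.0, 1.0],
                "label": ["target", "target", "decoy"],
                "accessions": ["ref|A|gene=G", "cont|DUST", "decoy_ref|A|gene=G"],
            }
        )
        _, confident = target_decoy_qvalues(df)
        assert list(confident["accessions"]) == ["ref|A|gene=G"]

    def test_plus_one_correction_is_more_conservative(self):
        df = self._frame([10.0, 9.0, 8.0, 8.5], ["target"] * 3 + ["decoy"])
        plain, _ = target_decoy_qvalues(df)
        corrected, _ = target_decoy_qvalues(df, plus_one=True)
        assert (corrected["q_value"] >= plain["q_value"]).all()

    def test_matches_brute_force_oracle_on_random_score_sets(self):
        rng = np.random.default_rng(19)
        for _ in range(100):
            n = int(rng.integers(2, 60))
            scores = np.round(rng.normal(0, 2, n), 1)  # ties likely
            labels = list(rng.choice(["target", "decoy"], n, p=[0.7, 0.3]))
            if "target" not in labels:
                labels[0] = "target"
            df = self._frame(list(scores), labels)
            scored, _ = target_decoy_qvalues(df)
            expected = brute_force_qvalues(list(scores), labels)
            assert np.allclose(scored["q_value"].to_numpy(), expected)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        df = self._frame(
            list(rng.normal(size=200)),
            list(rng.choice(["target", "decoy"], 200)),
        )
        sizes = [
            len(target_decoy_qvalues(df, threshold=t)[1])
            for t in (0.001, 0.01, 0.05, 0.2)
        ]
        assert sizes == sorted(sizes)


class TestMirrorAnnotation:
    def test_fully_matching_spectra_all_matched(self):
        s = spec([100.0, 200.0], [1.0, 2.0])
        v, ann = match_peaks(s, s)
        final = annotate_mirror(s, s, ann)
        assert set(final.observed) == {MATCHED}
        assert set(final.predicted) == {MATCHED}

    def test_missing_prediction_is_pink_category(self):
        observed = spec([100.0], [1.0])
        predicted = spec([100.0], [np.nan])
        _, ann = match_peaks(observed, predicted)
        final = annotate_mirror(observed, predicted, ann)
        assert final.observed == (MISSING_PREDICTION,)

    def test_zero_intensity_prediction_left_unannotated(self):
        observed = spec([100.0, 200.0], [1.0, 1.0])
        predicted = spec([100.0, 200.0], [0.0, 2.0])
        _, ann = match_peaks(observed, predicted)
        final = annotate_mirror(observed, predicted, ann)
        assert final.observed == (UNANNOTATED, MATCHED)
        assert final.predicted == (UNANNOTATED, MATCHED)

    def test_plot_mirror_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        from haplopept.psm_qc import plot_mirror

        observed = spec([100.0, 200.0, 300.0], [1.0, 2.0, 1.0])
        predicted = spec(
            [100.0, 200.0, 400.0], [1.0, np.nan, 2.0], labels=("b1", "y1", "b2")
        )
        _, ann = match_peaks(observed, predicted)
        ax = plot_mirror(observed, predicted, ann)
        assert ax is not None
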