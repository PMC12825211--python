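"""Likelihood filtering, median imputation, flattening, z-scoring, gating."""

import numpy as np
import pandas as pd
import pytest

import stimselect as ss
from stimselect.io import KeypointSeries
from stimselect.preprocess import (
    GatingError,
    ImputationError,
    epoch_tags,
    frame_speed,
    inverse_standardize,
)


def series_from(x, y, lik, bodyparts=None, fps=60.0):
    x = np.asarray(x, float)
    bodyparts = bodyparts or tuple(f"kp{i}" for i in range(x.shape[1]))
    return KeypointSeries(
        x=x, y=np.asarray(y, float), likelihood=np.asarray(lik, float),
        bodyparts=bodyparts, fps=fps,
    )


class TestFilter:
    def test_strict_threshold_masking(self):
        s = series_from([[1], [2], [3]], [[1], [2], [3]], [[0.9], [0.4], [0.6]])
        out = ss.filter_low_likelihood(s, 0.5)
        np.testing.assert_array_equal(out.mask()[:, 0], [False, True, False])
        assert out.n_masked == 1

    def test_threshold_zero_masks_nothing(self):
        s = series_from([[1], [2]], [[1], [2]], [[0.0], [0.3]])
        assert ss.filter_low_likelihood(s, 0.0).mask().sum() == 0

    def test_threshold_one_masks_all_below_one(self):
        s = series_from([[1], [2], [3]], [[1], [2], [3]], [[0.99], [1.0], [0.5]])
        np.testing.assert_array_equal(
            ss.filter_low_likelihood(s, 1.0).mask()[:, 0], [True, False, True]
        )

    def test_fully_masked_keypoint_warns_by_name(self):
        s = series_from([[1], [2]], [[1], [2]], [[0.1], [0.2]], bodyparts=("ankle",))
        with pytest.warns(UserWarning, match="ankle"):
            ss.filter_low_likelihood(s, 0.5)


class TestImpute:
    def test_masked_cell_takes_unmasked_median(self):
        s = series_from(
            [[1], [2], [3], [5]], [[10], [20], [30], [50]],
            [[0.9], [0.1], [0.9], [0.9]],
        )
        out = ss.impute_median(ss.filter_low_likelihood(s))
        assert out.x[1, 0] == 3.0  # median of 1, 3, 5
        assert out.y[1, 0] == 30.0

    def test_no_mask_is_identity(self):
        s = series_from([[1], [2]], [[3], [4]], [[0.9], [0.9]])
        out = ss.impute_median(s)
        np.testing.assert_array_equal(out.x, s.x)

    def test_all_but_one_masked_copies_single_observation(self):
        s = series_from(
            [[7], [1], [2]], [[8], [1], [2]], [[0.9], [0.1], [0.1]]
        )
        out = ss.impute_median(ss.filter_low_likelihood(s))
        np.testing.assert_array_equal(out.x[:, 0], [7, 7, 7])

    def test_fully_masked_keypoint_raises(self):
        s = series_from([[np.nan], [np.nan]], [[np.nan], [np.nan]], [[1], [1]])
        with pytest.raises(ImputationError):
            ss.impute_median(s)

    def test_windowed_variant_uses_local_median(self):
        x = np.array([[0], [0], [100], [10], [10]], float)
        s = series_from(x, x, [[0.9], [0.9], [0.1], [0.9], [0.9]])
        out = ss.impute_median(ss.filter_low_likelihood(s), window=3)
        assert out.x[2, 0] == 5.0  # median of neighbors 0 and 10


class TestFlatten:
    def test_pythagorean_magnitude(self):
        s = series_from([[3.0]], [[4.0]], [[0.9]])
        assert ss.flatten_euclidean(s).values[0, 0] == 5.0

    def test_origin_maps_to_zero(self):
        s = series_from([[0.0]], [[0.0]], [[0.9]])
        assert ss.flatten_euclidean(s).values[0, 0] == 0.0

    def test_hip_anchored_hip_column_is_zero(self):
        x = np.array([[10.0, 13.0], [20.0, 24.0]])
        s = series_from(x, x * 0 + 5, [[0.9, 0.9]] * 2, bodyparts=("hip", "knee"))
        out = ss.flatten_euclidean(s, origin="hip_anchored")
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0])
        assert out.values[0, 1] == pytest.approx(3.0)

    def test_invariant_to_likelihood_values(self):
        x = np.arange(6, dtype=float).reshape(3, 2)
        s1 = series_from(x, x, np.full((3, 2), 0.6))
        s2 = series_from(x, x, np.full((3, 2), 0.99))
        np.testing.assert_array_equal(
            ss.flatten_euclidean(s1).values, ss.flatten_euclidean(s2).values
        )


class TestStandardize:
    def test_population_convention(self):
        m = ss.flatten_euclidean(
            series_from([[1], [2], [3]], [[0], [0], [0]], [[1], [1], [1]])
        )
        z = ss.standardize(m)
        assert z.values[:, 0].mean() == pytest.approx(0, abs=1e-12)
        assert z.values[:, 0].std(ddof=0) == pytest.approx(1, abs=1e-12)

    def test_constant_column_rejected_by_name(self):
        m = ss.flatten_euclidean(
            series_from([[2], [2]], [[0], [0]], [[1], [1]], bodyparts=("heel",))
        )
        with pytest.raises(ValueError, match="heel"):
            ss.standardize(m)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 50, size=(40, 3))
        s = series_from(x, x * 2, np.ones_like(x))
        m = ss.flatten_euclidean(s)
        np.testing.assert_allclose(inverse_standardize(ss.standardize(m)), m.values,
                                   atol=1e-9)

    def test_affine_rescale_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 10, size=(30, 2))
        base = ss.PositionMatrix(values=v, keypoints=("a", "b"), fps=60)
        scaled = ss.PositionMatrix(values=3.5 * v + 7, keypoints=("a", "b"), fps=60)
        np.testing.assert_allclose(
            ss.standardize(base).values, ss.standardize(scaled).values, atol=1e-9
        )

    def test_standardize_is_idempotent(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(50, 2))
        m = ss.PositionMatrix(values=v, keypoints=("a", "b"), fps=60)
        z1 = ss.standardize(m)
        z2 = ss.standardize(ss.PositionMatrix(values=z1.values.copy(),
                                              keypoints=("a", "b"), fps=60))
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)


class TestMovementGate:
    @staticmethod
    def epochs_for(n_configs, on_f=60, off_f=60):
        rows = []
        f = 0
        for i in range(n_configs):
            rows.append({"label": i + 1, "mode": "TIS4", "on_start": f,
                         "on_stop": f + on_f, "off_start": f + on_f,
                         "off_stop": f + on_f + off_f})
            f += on_f + off_f
        return pd.DataFrame(rows)

    def test_static_trial_removes_everything(self):
        epochs = self.epochs_for(2)
        values = np.full((240, 2), 5.0)  # perfectly still limb
        m = ss.PositionMatrix(values=values, keypoints=("a", "b"), fps=60,
                              epoch_tag=epoch_tags(epochs, 240))
        gated = ss.movement_gate(m, epochs)
        assert not gated["retained"].any()

    def test_only_moving_configuration_retained(self):
        labels = [1, 2, 3]
        lib = ss.make_motif_library(labels, regime="selective", seed=5, noise_scale=0.0)
        # null out motifs 2 and 3: zero drive means no movement when stimulated
        from stimselect.synthgen import Motif, MotifLibrary
        quiet = tuple(
            m if i == 0 else Motif(A=m.A, drive=np.zeros(3), noise_scale=0.0)
            for i, m in enumerate(lib.motifs)
        )
        lib = MotifLibrary(motifs=quiet, emission=lib.emission,
                           rest_pose=lib.rest_pose, assignment=lib.assignment)
        spec = ss.TrialSpec(n_configs=3, noise_px=0.5, dropout_rate=0.0, seed=3)
        series, epochs, _ = ss.generate_trial(spec, lib)
        matrix = ss.preprocess_series(series, epochs)
        gated = ss.movement_gate(matrix, epochs)
        assert gated.set_index("label")["retained"].to_dict() == {
            1: True, 2: False, 3: False
        }

    def test_zero_k_sd_with_noise_retains_all(self):
        lib = ss.make_motif_library([1, 2], regime="selective", seed=6)
        spec = ss.TrialSpec(n_configs=2, noise_px=2.0, seed=6)
        series, epochs, _ = ss.generate_trial(spec, lib)
        matrix = ss.preprocess_series(series, epochs)
        gated = ss.movement_gate(matrix, epochs, k_sd=0.0)
        assert gated["retained"].all()

    def test_no_off_frames_raises(self):
        epochs = pd.DataFrame([{"label": 1, "mode": "TIS4", "on_start": 0,
                                "on_stop": 100, "off_start": 100, "off_stop": 100}])
        m = ss.PositionMatrix(values=np.random.default_rng(0).normal(size=(100, 2)),
                              keypoints=("a", "b"), fps=60,
                              epoch_tag=epoch_tags(epochs, 100))
        with pytest.raises(GatingError):
            ss.movement_gate(m, epochs)

    def test_speed_units(self):
        # 1-unit displacement per frame at 60 fps -> 60 units/s
        v = np.arange(10, dtype=float)[:, None]
        m = ss.PositionMatrix(values=v, keypoints=("a",), fps=60)
        np.testing.assert_allclose(frame_speed(m)[1:], 60.0)


class TestTrackingError:
    def test_identical_series_zero_error(self):
        x = np.random.default_rng(0).normal(size=(5, 2))
        s = series_from(x, x, np.ones_like(x))
        res = ss.evaluate_tracking_error(s, s, mm_per_px=0.5)
        assert res["overall_mm"] == 0.0
        assert all(v == 0.0 for v in res["per_keypoint_mm"].values())

    def test_constant_pixel_offset_scales_to_mm(self):
        x = np.zeros((4, 2))
        a = series_from(x, x, np.ones_like(x))
        b = series_from(x + 1.0, x, np.ones_like(x))
        res = ss.evaluate_tracking_error(a, b, mm_per_px=0.5)
        assert res["overall_mm"] == pytest.approx(0.5)

    def test_median_over_frames(self):
        xa = np.array([[0.0], [0.0], [0.0]])
        xb = np.array([[0.1], [0.3], [0.9]])
        a = series_from(xa, xa * 0, np.ones_like(xa), bodyparts=("hip",))
        b = series_from(xb, xa * 0, np.ones_like(xa), bodyparts=("hip",))
        res = ss.evaluate_tracking_error(a, b, mm_per_px=1.0)
        assert res["per_keypoint_mm"]["hip"] == pytest.approx(0.3)

    def test_schema_mismatch_rejected(self):
        x = np.zeros((2, 1))
        a = series_from(x, x, np.ones_like(x), bodyparts=("hip",))
        b = series_from(x, x, np.ones_like(x), bodyparts=("knee",))
        with pytest.raises(ValueError, match="schema"):
            ss.evaluate_tracking_error(a, b, mm_per_px=1.0)
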