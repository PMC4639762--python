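"""Reference correction, graphical transform and the windowed line fit."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from multipet import protocol, tac
from multipet.patlak import (
    ReferencePatlak,
    correct_reference_tac,
    ded_slope_pipeline,
    fit_patlak,
    patlak_transform,
)


class TestReferenceCorrection:
    def test_zero_k3_ref_identity(self, noise_free_pair):
        _, ref = noise_free_pair
        out = correct_reference_tac(ref, 0.0)
        assert np.array_equal(out.values, ref.values)

    def test_negative_k3_ref_rejected(self, noise_free_pair):
        with pytest.raises(ValueError):
            correct_reference_tac(noise_free_pair[1], -0.01)

    def test_output_never_exceeds_input(self, noise_free_pair):
        _, ref = noise_free_pair
        out = correct_reference_tac(ref, 0.01)
        assert np.all(out.values <= ref.values + 1e-12)

    def test_round_trip_recovers_free_curve(self, grid, input_fn, ded_schedule):
        """Forward-construct a trapped curve from a known free curve on the
        fine grid, frame-sample, correct — the free curve comes back."""
        free_fine = tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.0), input_fn, grid)
        trapped_fine = free_fine + 0.01 * cumulative_trapezoid(free_fine, grid, initial=0.0)
        trapped = tac.sample_frames(grid, trapped_fine, ded_schedule)
        free = tac.sample_frames(grid, free_fine, ded_schedule)
        recovered = correct_reference_tac(trapped, 0.01)
        late = ded_schedule.midpoints_min > 1.0
        rel = np.abs(recovered.values[late] - free.values[late]) / free.values[late]
        assert np.max(rel) < 0.01


class TestPatlakTransform:
    def test_target_equals_reference_gives_unit_y(self, noise_free_pair):
        _, ref = noise_free_pair
        pts = patlak_transform(ref, ref)
        assert np.allclose(pts.y, 1.0)

    def test_constant_reference_gives_x_equals_t(self, ded_schedule):
        const = tac.TimeActivityCurve(ded_schedule, np.full(ded_schedule.n_frames, 4.0))
        pts = patlak_transform(const, const)
        assert np.allclose(pts.x, ded_schedule.midpoints_min)

    def test_zero_reference_names_frame(self, ded_schedule):
        vals = np.ones(ded_schedule.n_frames)
        vals[5] = 0.0
        ref = tac.TimeActivityCurve(ded_schedule, vals)
        target = tac.TimeActivityCurve(ded_schedule, np.ones(ded_schedule.n_frames))
        with pytest.raises(ValueError, match="frame 5"):
            patlak_transform(target, ref)

    def test_schedule_mismatch_rejected(self, noise_free_pair):
        target, _ = noise_free_pair
        other = tac.TimeActivityCurve(
            protocol.FRAME_SCHEDULES["PIB"], np.ones(24)
        )
        with pytest.raises(ValueError):
            patlak_transform(target, other)

    def test_late_time_linearity(self, noise_free_pair):
        """2TCM target vs corrected reference: the late transform is a line."""
        target, ref = noise_free_pair
        pts = patlak_transform(target, correct_reference_tac(ref, 0.01))
        late = pts.midpoints_min >= 20.0
        x, y = pts.x[late], pts.y[late]
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - slope * x - intercept) ** 2)
        r2 = 1.0 - ss_res / np.sum((y - y.mean()) ** 2)
        assert r2 > 0.99


class TestFitPatlak:
    def test_exact_line_recovered(self, ded_schedule):
        from multipet.patlak import PatlakPoints

        t = ded_schedule.midpoints_min
        pts = PatlakPoints(t, x=t.copy(), y=0.03 * t + 1.2)
        res = fit_patlak(pts, window=(20.0, 60.0))
        assert res.slope == pytest.approx(0.03, abs=1e-12)
        assert res.intercept == pytest.approx(1.2, abs=1e-10)

    def test_unit_y_gives_zero_slope_unit_intercept(self, noise_free_pair):
        _, ref = noise_free_pair
        res = fit_patlak(patlak_transform(ref, ref))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_rejected(self, noise_free_pair):
        _, ref = noise_free_pair
        pts = patlak_transform(ref, ref)
        with pytest.raises(ValueError, match="need >= 3"):
            fit_patlak(pts, window=(58.0, 60.0))


class TestPipeline:
    def test_identical_curves_give_zero_slope(self, noise_free_pair):
        _, ref = noise_free_pair
        res = ded_slope_pipeline(ref, ref, k3_ref=0.0)
        assert abs(res.slope) < 1e-12

    def test_reversible_target_gives_null_slope(self, grid, input_fn, ded_schedule):
        # irreversible-trapping pipeline on a k3 = 0 target: slope ~ 0
        target = tac.sample_frames(
            grid, tac.tissue_tac(tac.KineticParams(0.25, 0.2, 0.0), input_fn, grid), ded_schedule
        )
        ref = tac.sample_frames(
            grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.0), input_fn, grid), ded_schedule
        )
        res = ded_slope_pipeline(target, ref, k3_ref=0.0)
        assert abs(res.slope) < 1e-4

    def test_carrier_preset_exceeds_noncarrier(self, grid, input_fn, ded_schedule, noise_free_pair):
        _, ref = noise_free_pair
        carrier = tac.sample_frames(
            grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.055), input_fn, grid), ded_schedule
        )
        noncarrier = tac.sample_frames(
            grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, 0.035), input_fn, grid), ded_schedule
        )
        assert (
            ded_slope_pipeline(carrier, ref).slope > ded_slope_pipeline(noncarrier, ref).slope
        )

    def test_correction_raises_apparent_slope(self, noise_free_pair):
        target, ref = noise_free_pair
        corrected = ded_slope_pipeline(target, ref, k3_ref=0.01)
        uncorrected = ded_slope_pipeline(target, ref, k3_ref=0.0)
        assert corrected.slope > uncorrected.slope

    def test_slope_increasing_in_k3(self, grid, input_fn, ded_schedule, noise_free_pair):
        _, ref = noise_free_pair
        slopes = []
        for k3 in np.arange(0.01, 0.101, 0.01):
            target = tac.sample_frames(
                grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, k3), input_fn, grid), ded_schedule
            )
            slopes.append(ded_slope_pipeline(target, ref).slope)
        assert np.all(np.diff(slopes) > 0)

    def test_linearization_residual_small(self, noise_free_pair):
        # the stated purpose of the reference correction: a linear late plot
        target, ref = noise_free_pair
        model = ReferencePatlak().fit(target, ref)
        late = (model.points_.midpoints_min >= 20) & (model.points_.midpoints_min <= 60)
        assert model.residual_sd_ < 0.01 * model.points_.y[late].mean()

    @pytest.mark.parametrize("k3", [0.03, 0.06, 0.10])
    def test_noise_bias_below_ten_percent(self, grid, input_fn, ded_schedule, noise_free_pair, k3):
        _, ref = noise_free_pair
        target = tac.sample_frames(
            grid, tac.tissue_tac(tac.KineticParams(0.3, 0.2, k3), input_fn, grid), ded_schedule
        )
        truth = ded_slope_pipeline(target, ref).slope
        rng = np.random.default_rng(99)
        estimates = [
            ded_slope_pipeline(tac.add_noise(target, 0.05, rng), ref).slope for _ in range(200)
        ]
        assert abs(np.mean(estimates) - truth) < 0.10 * truth

    def test_estimator_api(self, noise_free_pair):
        target, ref = noise_free_pair
        model = ReferencePatlak(k3_ref=0.01, window=(20, 60))
        assert model.get_params()["k3_ref"] == 0.01
        model.fit(target, ref)
        assert model.n_points_ >= 3
        assert model.predict(0.0) == pytest.approx(model.intercept_)
        fresh = ReferencePatlak().set_params(k3_ref=0.02)
        with pytest.raises(AttributeError):
            fresh.predict(1.0)
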