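import dataclasses

import numpy as np
import pandas as pd
import pytest

from optonotch import kinetics, synthgen
from optonotch.kinetics import ActivationCurve, saturating_exponential


def _model_curve(k, t0, n_max, length, times=None):
    times = np.arange(0.0, 40.0, 0.5) if times is None else times
    y = saturating_exponential(times, n_max / length, k, t0)
    return ActivationCurve(times=times, density=y, region_length_um=length)


class TestBuildCurve:
    def test_density_is_count_over_length(self, small_spot_movie):
        params, stack, truth = small_spot_movie
        from optonotch import spotcall
        spots = spotcall.detect_spots(stack, spotcall.SpotCallConfig(min_intensity=12000))
        curve = kinetics.build_activation_curve(spots, region_length_um=50.0)
        np.testing.assert_allclose(curve.density, spots.counts_per_frame() / 50.0)

    def test_alignment_shifts_times_not_densities(self, small_spot_movie):
        _, stack, _ = small_spot_movie
        from optonotch import spotcall
        spots = spotcall.detect_spots(stack, spotcall.SpotCallConfig(min_intensity=12000))
        a = kinetics.build_activation_curve(spots, 50.0, alignment_time=0.0)
        b = kinetics.build_activation_curve(spots, 50.0, alignment_time=55.0)
        np.testing.assert_allclose(a.times - 55.0, b.times)
        np.testing.assert_allclose(a.density, b.density)

    def test_curve_matches_ground_truth_cumulative_onsets(self, small_spot_movie):
        """Perfect detection: curve equals cumulative onset count / length."""
        params, stack, truth = small_spot_movie
        from optonotch import spotcall
        spots = spotcall.detect_spots(stack, spotcall.SpotCallConfig(min_intensity=12000))
        got = kinetics.build_activation_curve(spots, params.region_length_um)
        oracle = kinetics.curve_from_onsets(
            truth.onset_times, truth.frame_times, params.region_length_um
        )
        # noise-free movie, clear spots: detected counts track the truth
        assert np.abs(got.counts - oracle.counts).max() <= 1

    def test_empty_spotset_gives_zero_curve(self):
        from optonotch.spotcall import SpotSet
        empty = SpotSet(table=pd.DataFrame(columns=["frame", "x_px", "y_px"]),
                        n_frames=5, frame_times_min=np.arange(5.0))
        curve = kinetics.build_activation_curve(empty, 10.0)
        assert np.all(curve.density == 0)

    def test_invalid_length_rejected(self, small_spot_movie):
        _, stack, _ = small_spot_movie
        from optonotch import spotcall
        spots = spotcall.detect_spots(stack.with_data(stack.data[:1]))
        with pytest.raises(ValueError):
            kinetics.build_activation_curve(spots, region_length_um=0.0)


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_curves_recovered_to_1e6(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.uniform(0.05, 1.0)
        t0 = rng.uniform(2.0, 20.0)
        n_max, length = rng.uniform(20, 100), rng.uniform(30, 100)
        fit = kinetics.fit_activation(_model_curve(k, t0, n_max, length), n_max)
        assert fit.converged
        assert abs(fit.k - k) / k < 1e-6
        assert abs(fit.t0 - t0) / t0 < 1e-6

    def test_all_zero_curve_flagged_not_zero(self):
        curve = ActivationCurve(times=np.arange(10.0), density=np.zeros(10))
        fit = kinetics.fit_activation(curve, 60)
        assert not fit.converged
        assert np.isnan(fit.k) and np.isnan(fit.t0)

    def test_leading_zero_padding_does_not_change_fit(self):
        base = _model_curve(0.4, 10.0, 60, 50, times=np.arange(5.0, 40.0, 0.5))
        padded = _model_curve(0.4, 10.0, 60, 50, times=np.arange(0.0, 40.0, 0.5))
        f1 = kinetics.fit_activation(base, 60)
        f2 = kinetics.fit_activation(padded, 60)
        assert f1.k == pytest.approx(f2.k, rel=1e-6)
        assert f1.t0 == pytest.approx(f2.t0, rel=1e-6)

    def test_stochastic_recovery_median_within_10_percent(self):
        """20 replicate embryos at the default regime: median |dk|/k <= 0.10."""
        true_k = 0.3
        errs, t0_errs = [], []
        for seed in range(1, 21):
            p = synthgen.SpotMovieParams(seed=seed, min_frame_px=16)
            _, truth = synthgen.gen_spot_movie(p)
            curve = kinetics.curve_from_onsets(
                truth.onset_times, p.frame_times, p.region_length_um
            )
            fit = kinetics.fit_activation(curve, p.n_nuclei)
            errs.append(abs(fit.k - true_k) / true_k)
            t0_errs.append(abs(fit.t0 - p.onset_delay_t0))
        assert np.median(errs) <= 0.10
        assert np.median(t0_errs) <= p.frame_interval

    def test_doubling_true_rate_increases_estimates(self):
        medians = []
        for true_k in (0.1, 0.2, 0.4):
            ks = []
            for seed in range(1, 9):
                p = synthgen.SpotMovieParams(onset_rate_k=true_k, seed=seed,
                                             min_frame_px=16)
                _, truth = synthgen.gen_spot_movie(p)
                curve = kinetics.curve_from_onsets(
                    truth.onset_times, p.frame_times, p.region_length_um
                )
                ks.append(kinetics.fit_activation(curve, p.n_nuclei).k)
            medians.append(np.median(ks))
        assert medians[0] < medians[1] < medians[2]

    def test_deterministic_given_inputs(self):
        curve = _model_curve(0.25, 8.0, 60, 50)
        f1 = kinetics.fit_activation(curve, 60)
        f2 = kinetics.fit_activation(curve, 60)
        assert (f1.k, f1.t0, f1.rss) == (f2.k, f2.t0, f2.rss)


def _fake_fit(k, t0, condition):
    curve = ActivationCurve(times=np.arange(3.0), density=np.zeros(3), condition=condition)
    return kinetics.ActivationKineticsResults(
        k=k, t0=t0, n_max=60, rss=0.0, n_points=3, converged=True, curve=curve
    )


class TestCompareConditions:
    def test_identical_groups_give_p_near_one_and_zero_delta(self):
        fits = [_fake_fit(0.2, 10.0, "control") for _ in range(4)]
        fits += [_fake_fit(0.2, 10.0, "treated") for _ in range(4)]
        # tiny jitter so variances are nonzero
        for i, f in enumerate(fits):
            f.k += 1e-6 * (i % 2)
            f.t0 += 1e-6 * (i % 2)
        table = kinetics.compare_conditions(fits, control="control")
        row = table.loc["treated"]
        assert row.delta_rate == pytest.approx(0.0, abs=1e-9)
        assert row.p_rate > 0.9

    def test_single_embryo_condition_reported_without_p_value(self):
        fits = [_fake_fit(0.2, 10.0, "control") for _ in range(3)]
        fits.append(_fake_fit(0.1, 12.0, "single"))
        table = kinetics.compare_conditions(fits, control="control")
        assert np.isnan(table.loc["single", "p_rate"])
        assert table.loc["single", "n_embryos"] == 1

    def test_large_rate_difference_detected_with_high_power(self):
        """k = 0.2 vs 0.05, n = 6 embryos: the Welch test nearly always rejects."""
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 30
        for _ in range(reps):
            fits = []
            for cond, k in (("control", 0.2), ("late", 0.05)):
                # MLE-distributed rate estimates for 60 observed onsets
                for _ in range(6):
                    k_hat = k * 60 / rng.gamma(60, 1.0)
                    fits.append(_fake_fit(k_hat, 10.0, cond))
            table = kinetics.compare_conditions(fits, control="control")
            rejections += table.loc["late", "p_rate"] < 0.05
        assert rejections >= 0.9 * reps

    def test_null_type_one_error_calibrated(self):
        """Equal-rate groups: rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(1)
        reps, rejections = 1000, 0
        for _ in range(reps):
            fits = []
            for cond in ("control", "same"):
                for _ in range(6):
                    k_hat = 0.2 * 60 / rng.gamma(60, 1.0)
                    fits.append(_fake_fit(k_hat, 10.0, cond))
            table = kinetics.compare_conditions(fits, control="control")
            rejections += table.loc["same", "p_rate"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_missing_control_condition_raises(self):
        with pytest.raises(ValueError, match="control"):
            kinetics.compare_conditions([_fake_fit(0.2, 10, "a")], control="control")


class TestStability:
    def test_constant_intensities_give_zero_cvs(self):
        rows = [
            {"nucleus_id": n, "frame": f, "intensity": 100.0}
            for n in range(5) for f in range(4)
        ]
        rep = kinetics.spot_intensity_stability(pd.DataFrame(rows))
        assert rep.cv_over_time == 0.0
        assert rep.cv_within_timepoint == 0.0

    def test_generator_cvs_recovered_from_ground_truth_amplitudes(self):
        """Default generator CVs (75% between spots, 20% over time) recovered
        within 20% relative from the recorded amplitudes."""
        p = synthgen.SpotMovieParams(onset_delay_t0=0.0, movie_start=10.0,
                                     movie_end=29.5, min_frame_px=16, seed=9)
        _, truth = synthgen.gen_spot_movie(p)
        rows = []
        for ti in range(len(truth.frame_times)):
            for n in range(p.n_nuclei):
                a = truth.amplitudes[ti, n]
                if np.isfinite(a):
                    rows.append({"nucleus_id": n, "frame": ti, "intensity": a})
        rep = kinetics.spot_intensity_stability(pd.DataFrame(rows))
        assert rep.cv_over_time == pytest.approx(0.20, rel=0.20)
        # within a frame, between-spot and temporal variation compound
        expected_within = np.sqrt((1 + 0.75**2) * (1 + 0.20**2) - 1)
        assert rep.cv_within_timepoint == pytest.approx(expected_within, rel=0.20)
        assert rep.cv_within_timepoint > rep.cv_over_time

    def test_permuting_frame_labels_keeps_within_frame_cv(self):
        rng = np.random.default_rng(2)
        rows = [
            {"nucleus_id": n, "frame": f, "intensity": rng.lognormal(0, 0.5)}
            for n in range(30) for f in range(10)
        ]
        df = pd.DataFrame(rows)
        base = kinetics.spot_intensity_stability(df)
        perms = []
        for _ in range(20):
            shuffled = df.copy()
            shuffled["frame"] = rng.permutation(shuffled["frame"].to_numpy())
            perms.append(kinetics.spot_intensity_stability(shuffled).cv_within_timepoint)
        assert np.mean(perms) == pytest.approx(base.cv_within_timepoint, rel=0.1)

    def test_insufficient_data_errors(self):
        one_frame = pd.DataFrame(
            [{"nucleus_id": n, "frame": 0, "intensity": 1.0} for n in range(3)]
        )
        with pytest.raises(ValueError, match="2 frames"):
            kinetics.spot_intensity_stability(one_frame)


def test_percent_of_control_scales_density():
    curve = ActivationCurve(times=np.arange(3.0), density=np.array([0.0, 0.1, 0.2]))
    np.testing.assert_allclose(
        kinetics.percent_of_control(curve, 0.2), [0.0, 50.0, 100.0]
    )
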