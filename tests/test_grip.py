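"""Grip-metric extraction: oracle values, detector behaviour, invariances."""

import numpy as np
import pytest

from connectogrip.grip import (
    DigitForceTrial,
    GripConfig,
    GripError,
    HandSummary,
    baseline_stats,
    compute_ratios,
    compute_trial_metrics,
    detect_offset,
    detect_onset,
    direction_error,
    grip_force_series,
    magnitude_error,
    peak_strength,
)

from conftest import make_target_trial


def _flat_trial(fn_thumb, fn_index, n=600, fs=500.0, kind="max_grip"):
    t = np.arange(n) / fs
    forces = {
        "thumb": np.column_stack([np.full(n, fn_thumb), np.zeros(n), np.zeros(n)]),
        "index": np.column_stack([np.full(n, fn_index), np.zeros(n), np.zeros(n)]),
    }
    return DigitForceTrial(
        sampling_rate=fs, time=t, forces=forces, cue_grip=0.6, cue_rest=1.0 if kind == "target_grip" else None,
        trial_kind=kind, hand="paretic",
    )


class TestGripForceSeries:
    @pytest.mark.parametrize("thumb,index,expected", [(4, 4, 4), (2, 6, 4), (0, 4, 2)])
    def test_mean_of_digit_normals(self, thumb, index, expected):
        series = grip_force_series(_flat_trial(thumb, index))
        assert np.allclose(series, expected)

    def test_sum_combine(self):
        series = grip_force_series(_flat_trial(2, 6), GripConfig(digit_combine="sum"))
        assert np.allclose(series, 8)

    def test_missing_digit_named_in_error(self):
        trial = _flat_trial(4, 4)
        del trial.forces["index"]
        with pytest.raises(GripError, match="index"):
            grip_force_series(trial)


class TestBaseline:
    def test_constant_baseline(self):
        t = np.arange(500) / 500.0
        mean, sd = baseline_stats(np.full(500, 0.5), t, cue_grip=0.6, window_s=0.5)
        assert mean == pytest.approx(0.5)
        assert sd == 0.0

    def test_textbook_sample_sd(self):
        t = np.arange(3) * 0.1
        mean, sd = baseline_stats(np.array([1.0, 2.0, 3.0]), t, cue_grip=0.25, window_s=0.3, min_samples=3)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(0.3, 0.05, 2500)
        t = np.arange(2500) / 500.0
        mean, sd = baseline_stats(vals, t, cue_grip=5.0, window_s=5.0)
        # independent two-pass computation
        m = sum(vals) / len(vals)
        s = (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        assert mean == pytest.approx(m, abs=1e-12)
        assert sd == pytest.approx(s, abs=1e-12)

    def test_too_few_samples(self):
        t = np.arange(100) / 500.0
        with pytest.raises(GripError, match="baseline"):
            baseline_stats(np.zeros(100), t, cue_grip=0.01, window_s=0.005)


class TestOnsetOffset:
    def test_step_onset_within_one_sample(self):
        fs = 500.0
        t = np.arange(2000) / fs
        series = np.where(t >= 1.2, 1.0, 0.0)
        rt = detect_onset(series, t, cue_grip=1.0, baseline_mean=0.0, baseline_sd=0.01)
        assert rt == pytest.approx(0.2, abs=1.0 / fs)

    def test_no_crossing_is_invalid_not_exception(self):
        t = np.arange(2000) / 500.0
        assert detect_onset(np.zeros(2000), t, 1.0, 0.0, 0.01) is None

    def test_already_above_threshold_at_cue(self):
        t = np.arange(2000) / 500.0
        rt = detect_onset(np.ones(2000), t, 1.0, 0.0, 0.01)
        assert 0.0 <= rt <= 1.0 / 500.0

    def test_exponential_decay_offset(self):
        fs = 500.0
        t = np.arange(3000) / fs
        cue_rest = 2.0
        # 4 N hold, exponential decay after the rest cue crossing 3*sd at +0.35 s
        sd = 0.01
        thr = 3 * sd
        tau = 0.35 / np.log(4.0 / thr)
        series = np.where(t < cue_rest, 4.0, 4.0 * np.exp(-(t - cue_rest) / tau))
        rt = detect_offset(series, t, cue_rest, 0.0, sd)
        assert rt == pytest.approx(0.35, abs=1.0 / fs)

    def test_already_at_baseline(self):
        t = np.arange(2000) / 500.0
        rt = detect_offset(np.zeros(2000), t, 1.0, 0.0, 0.01)
        assert 0.0 <= rt <= 1.0 / 500.0

    def test_never_returns_is_invalid(self):
        t = np.arange(2000) / 500.0
        assert detect_offset(np.full(2000, 4.0), t, 1.0, 0.0, 0.01) is None

    def test_sustain_rejects_single_sample_spike(self):
        t = np.arange(2000) / 500.0
        series = np.zeros(2000)
        series[700] = 5.0  # 1.4 s: isolated spike
        series[t >= 1.8] = 5.0
        rt = detect_onset(series, t, 1.0, 0.0, 0.01)
        assert rt == pytest.approx(0.8, abs=1.0 / 500.0)

    def test_detectors_match_linear_scan_oracle(self):
        """Randomized planted latencies: detector equals an exhaustive scan."""
        cfg = GripConfig()
        rng = np.random.default_rng(11)
        fs = 500.0
        for _ in range(30):
            reaction = rng.uniform(0.1, 1.2)
            relaxation = rng.uniform(0.06, 1.2)
            trial = make_target_trial(
                reaction=reaction, relaxation=relaxation, noise_sd=0.005, seed=int(rng.integers(1 << 30))
            )
            series = grip_force_series(trial, cfg)
            mean, sd = baseline_stats(series, trial.time, trial.cue_grip, cfg.baseline_window_s)
            thr = mean + 3 * max(sd, cfg.sd_floor_N)
            n_sustain = int(round(cfg.sustain_s * fs))

            def scan(cond_fn, start_time):
                idx = [i for i, t in enumerate(trial.time) if t >= start_time]
                for i in idx:
                    if trial.time[i] > start_time + cfg.max_latency_s:
                        break
                    run = series[i : i + n_sustain]
                    if len(run) and all(cond_fn(v) for v in run):
                        return trial.time[i] - start_time
                return None

            onset = detect_onset(series, trial.time, trial.cue_grip, mean, sd, cfg)
            offset = detect_offset(series, trial.time, trial.cue_rest, mean, sd, cfg)
            assert onset == pytest.approx(scan(lambda v: v > thr, trial.cue_grip), abs=1e-12)
            assert offset == pytest.approx(scan(lambda v: v <= thr, trial.cue_rest), abs=1e-12)


class TestAmplitudeMetrics:
    def test_triangular_ramp_peak(self):
        n, fs = 1500, 500.0
        t = np.arange(n) / fs
        env = np.interp(t, [0.5, 1.5, 2.5], [0, 30.0, 0])
        forces = {d: np.column_stack([env, np.zeros(n), np.zeros(n)]) for d in ("thumb", "index")}
        trial = DigitForceTrial(fs, t, forces, 0.5, "max_grip", "paretic")
        assert peak_strength(trial) == pytest.approx(30.0)

    def test_constant_peak_and_noisy_max_oracle(self):
        assert peak_strength(_flat_trial(10, 10)) == pytest.approx(10.0)
        rng = np.random.default_rng(5)
        n = 1000
        t = np.arange(n) / 500.0
        env = np.linspace(0, 20, n) + rng.normal(0, 0.5, n)
        forces = {d: np.column_stack([env, np.zeros(n), np.zeros(n)]) for d in ("thumb", "index")}
        trial = DigitForceTrial(500.0, t, forces, 0.1, "max_grip", "paretic")
        assert peak_strength(trial) == pytest.approx(max(env))

    @pytest.mark.parametrize("hold,expected", [(5.0, 1.0), (4.0, 0.0)])
    def test_magnitude_error_constant_hold(self, hold, expected):
        trial = make_target_trial(hold=hold)
        assert magnitude_error(trial, onset_s=0.3) == pytest.approx(expected, abs=1e-9)

    def test_magnitude_error_symmetric_ramp_cancels(self):
        trial = make_target_trial(hold=4.0)
        # superimpose a hold-window-symmetric ramp 3 -> 5 N
        cfg = GripConfig()
        t = trial.time
        lo, hi = trial.cue_grip + 0.3 + cfg.transient_s, trial.cue_rest
        mask = (t >= lo) & (t <= hi)
        ramp = np.interp(t, [lo, hi], [-1.0, 1.0])
        for d in trial.forces:
            trial.forces[d][mask, 0] += ramp[mask]
        assert magnitude_error(trial, onset_s=0.3) == pytest.approx(0.0, abs=1e-6)

    def test_empty_hold_window_invalid(self):
        trial = make_target_trial(reaction=0.3)
        cfg = GripConfig(transient_s=5.0)  # pushes window past cue_rest
        assert magnitude_error(trial, onset_s=0.3, config=cfg) is None


class TestDirectionError:
    def _angle_trial(self, fn, ft1, ft2):
        trial = make_target_trial(hold=1.0)
        mask = np.ones(trial.time.size, dtype=bool)
        for d in trial.forces:
            trial.forces[d][:, 0] = fn
            trial.forces[d][:, 1] = ft1
            trial.forces[d][:, 2] = ft2
        return trial

    @pytest.mark.parametrize(
        "fn,ft1,ft2,expected",
        [(5.0, 0.0, 0.0, 0.0), (4.0, 3.0, 0.0, 36.8699), (0.0, 5.0, 0.0, 90.0)],
    )
    def test_analytic_angles(self, fn, ft1, ft2, expected):
        trial = self._angle_trial(fn, ft1, ft2)
        assert direction_error(trial, onset_s=0.3) == pytest.approx(expected, abs=1e-4)

    def test_invariant_to_shear_rotation_and_scaling(self):
        base = self._angle_trial(4.0, 3.0, 0.0)
        ref = direction_error(base, onset_s=0.3)
        for phi, scale in [(0.7, 1.0), (2.1, 3.5), (4.0, 0.2)]:
            rot = self._angle_trial(4.0 * scale, 3.0 * scale * np.cos(phi), 3.0 * scale * np.sin(phi))
            assert direction_error(rot, onset_s=0.3) == pytest.approx(ref, abs=1e-9)

    def test_all_below_floor_invalid(self):
        trial = self._angle_trial(0.0, 0.0, 0.0)
        assert direction_error(trial, onset_s=0.3) is None


class TestRatios:
    @pytest.mark.parametrize(
        "p,n,expected", [(10.0, 10.0, 0.5), (0.6, 0.4, 0.6), (0.0, 20.0, 0.0)]
    )
    def test_ratio_arithmetic(self, p, n, expected):
        ph = HandSummary("paretic", means={"strength": p}, counts={"strength": 3})
        nh = HandSummary("nonparetic", means={"strength": n}, counts={"strength": 3})
        out = compute_ratios(ph, nh)
        assert out.ratios["strength"] == pytest.approx(expected)

    def test_both_zero_gives_undefined_with_warning(self, caplog):
        ph = HandSummary("paretic", means={"strength": 0.0}, counts={"strength": 3})
        nh = HandSummary("nonparetic", means={"strength": 0.0}, counts={"strength": 3})
        out = compute_ratios(ph, nh)
        assert out.ratios["strength"] is None
        assert any("zero" in r.message for r in caplog.records)

    def test_monotone_in_paretic_value(self):
        nh = HandSummary("nonparetic", means={"strength": 5.0}, counts={"strength": 3})
        vals = []
        for p in (1.0, 2.0, 5.0, 9.0):
            ph = HandSummary("paretic", means={"strength": p}, counts={"strength": 3})
            vals.append(compute_ratios(ph, nh).ratios["strength"])
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)


def test_metrics_invariant_to_joint_time_shift():
    trial = make_target_trial(reaction=0.4, relaxation=0.3, hold=4.5, theta_deg=12.0)
    ref = compute_trial_metrics(trial)
    shifted = make_target_trial(reaction=0.4, relaxation=0.3, hold=4.5, theta_deg=12.0)
    shift = 7.25
    shifted.time = shifted.time + shift
    shifted.cue_grip += shift
    shifted.cue_rest += shift
    out = compute_trial_metrics(shifted)
    for key, val in ref.as_dict().items():
        if val is None:
            assert out.as_dict()[key] is None
        else:
            assert out.as_dict()[key] == pytest.approx(val, abs=1e-9)
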