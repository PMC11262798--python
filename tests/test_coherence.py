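import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal.windows import hann

import thetabmi as tb
from thetabmi.coherence import (
    BaselineStats,
    ThresholdProfile,
    WindowSpec,
    artifact_verdict,
    calibrate_thresholds,
    compute_baseline,
    detrend_poly3,
    iter_epochs,
    msc_welch,
    stream_detect,
    theta_summary,
    welch_segment_count,
    zscore_with_baseline,
)

FS = 2000.0


def welch_coherence_bias(nperseg: int, step: int, n_segments: int) -> float:
    """Independent oracle: expected MSC of independent noise for a Hann
    Welch estimate with overlapped segments, 1/K_eff with K_eff from the
    window overlap correlations."""
    w = hann(nperseg)
    denom = float(np.sum(w * w))
    rho = np.array(
        [
            np.sum(w[: nperseg - m * step] * w[m * step :]) / denom if m * step < nperseg else 0.0
            for m in range(1, n_segments)
        ]
    )
    k_eff = n_segments**2 / (n_segments + 2 * np.sum((n_segments - np.arange(1, n_segments)) * rho**2))
    return 1.0 / k_eff


class TestDetrendPoly3:
    def test_exact_cubic_maps_to_zero(self):
        t = np.linspace(0, 1.25, 2500)
        x = 4.0 - 3.2 * t + 0.7 * t**2 - 5.1 * t**3
        out = detrend_poly3(x)
        assert np.max(np.abs(out)) < 1e-9 * np.max(np.abs(x))

    def test_constant_maps_to_zero(self):
        out = detrend_poly3(np.full(2500, 7.3))
        assert np.max(np.abs(out)) < 1e-9

    def test_cubic_plus_sinusoid_matches_projection_oracle(self):
        # independent oracle: subtracting the least-squares cubic leaves the
        # sine minus its own cubic projection (a sine over a finite window is
        # not orthogonal to the cubic subspace, so the sine itself is not the
        # exact residual)
        t = np.linspace(0, 1.25, 2500)
        sine = np.sin(2 * np.pi * 8.0 * t)
        x = (2.0 + t - 0.5 * t**3) * 100 + sine
        vander = np.vander(t, 4)
        coef, *_ = np.linalg.lstsq(vander, sine, rcond=None)
        expected = sine - vander @ coef
        out = detrend_poly3(x)
        assert np.linalg.norm(out - expected) / np.linalg.norm(sine) < 1e-9
        # the oscillatory content itself is preserved: the 8 Hz Fourier
        # amplitude survives trend removal essentially unchanged
        amp = lambda v: np.abs(np.fft.rfft(v))[10]  # 8 Hz bin (10 cycles)
        assert amp(out) == pytest.approx(amp(sine), rel=0.02)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            detrend_poly3(np.zeros(7))


class TestZscore:
    def test_window_at_baseline_mean_is_zero(self):
        b = BaselineStats(mean=5.0, sd=2.0)
        assert np.all(zscore_with_baseline(np.full(10, 5.0), b) == 0)

    def test_arithmetic(self):
        b = BaselineStats(mean=0.0, sd=2.0)
        assert zscore_with_baseline(np.array([8.0]), b)[0] == 4.0

    def test_identity_under_unit_baseline(self, rng):
        x = rng.standard_normal(100)
        b = BaselineStats(mean=0.0, sd=1.0)
        assert np.allclose(zscore_with_baseline(zscore_with_baseline(x, b), b), x)


class TestMscWelch:
    def test_identical_signals_give_unit_coherence(self, rng, window_spec):
        x = rng.standard_normal(2500)
        coh = msc_welch(x, x, window_spec, FS)
        assert np.allclose(coh, 1.0)

    def test_scale_and_sign_invariance(self, rng, window_spec):
        x = rng.standard_normal(2500)
        y = rng.standard_normal(2500)
        base = msc_welch(x, y, window_spec, FS)
        assert np.allclose(msc_welch(3.7 * x, y, window_spec, FS), base)
        assert np.allclose(msc_welch(x, -0.2 * y, window_spec, FS), base)

    def test_values_bounded(self, rng, window_spec):
        for _ in range(10):
            coh = msc_welch(rng.standard_normal(2500), rng.standard_normal(2500), window_spec, FS)
            assert np.all((coh >= 0) & (coh <= 1))

    def test_zero_variance_flagged(self, window_spec, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            msc_welch(np.zeros(2500), rng.standard_normal(2500), window_spec, FS)

    def test_independent_noise_matches_welch_bias_oracle(self, rng, window_spec):
        k = welch_segment_count(window_spec, FS)
        expected = welch_coherence_bias(1000, 500, k)
        means = [
            msc_welch(rng.standard_normal(2500), rng.standard_normal(2500), window_spec, FS).mean()
            for _ in range(400)
        ]
        assert np.mean(means) == pytest.approx(expected, rel=0.2)


class TestThetaSummary:
    def test_constant_spectrum(self, window_spec):
        theta, delta = theta_summary(np.full(window_spec.freq_grid.size, 0.6), window_spec)
        assert theta == pytest.approx(0.6)
        assert delta == pytest.approx(0.6)

    def test_band_membership_is_inclusive(self, window_spec):
        assert window_spec.band_mask((6.0, 11.0)).sum() == 11
        assert window_spec.band_mask((1.0, 4.0)).sum() == 7

    def test_single_grid_point_indicator(self, window_spec):
        coh = (window_spec.freq_grid == 8.0).astype(float)
        theta, _ = theta_summary(coh, window_spec)
        assert theta == pytest.approx(1.0 / 11.0)

    def test_empty_band_rejected(self):
        spec = WindowSpec()
        with pytest.raises(ValueError, match="no grid points"):
            coh = np.zeros(spec.freq_grid.size)
            theta_summary(coh, WindowSpec(theta_band=(6.25, 6.3)))


class TestArtifactVerdict:
    def test_just_over_one_percent_is_saturated(self, rng):
        z = rng.standard_normal(2500) * 0.5
        z[:30] = 5.0  # 30/2500 = 1.2% > 1%
        assert artifact_verdict(z, rng.standard_normal(2500) * 0.5, 0.6, 0.3) == "saturated"

    def test_exactly_one_percent_passes_to_delta_check(self, rng):
        z = rng.standard_normal(2500) * 0.5
        z[:25] = 5.0  # exactly 1%: strict inequality, not saturated
        other = rng.standard_normal(2500) * 0.5
        assert artifact_verdict(z, other, 0.6, 0.3) == "clean"
        assert artifact_verdict(z, other, 0.5, 0.8) == "delta_dominant"

    def test_saturation_precedes_delta_check(self, rng):
        z = np.full(2500, 5.0)
        assert artifact_verdict(z, z, 0.1, 0.9) == "saturated"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            artifact_verdict(np.zeros(10), np.zeros(11), 0.5, 0.1)


class TestCalibration:
    def test_two_value_hand_arithmetic(self):
        prof = calibrate_thresholds([0.4, 0.6], subject_id="r1")
        assert prof.mean == pytest.approx(0.5)
        assert prof.sd == pytest.approx(np.sqrt(0.02), abs=1e-12)  # n-1 denominator
        assert prof.high - prof.low == pytest.approx(2 * prof.sd)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_thresholds([0.5, 0.5, 0.5])

    def test_truncated_normal_recovery(self, rng):
        vals = np.clip(rng.normal(0.5, 0.1, 10000), 0, 1)
        prof = calibrate_thresholds(vals)
        assert prof.mean == pytest.approx(0.5, abs=0.01)
        assert prof.sd == pytest.approx(0.1, abs=0.01)

    def test_profile_text_round_trip(self):
        prof = calibrate_thresholds([0.3, 0.5, 0.7], subject_id="r2")
        back = ThresholdProfile.from_text(prof.to_text())
        assert back.mean == prof.mean and back.sd == prof.sd
        assert back.subject_id == "r2"


@pytest.fixture(scope="module")
def calibrated(coupled_pair):
    x, y, states, bx, by = coupled_pair
    spec = WindowSpec()
    values = [e.theta_value for e in iter_epochs(x, y, bx, by, spec) if e.clean]
    return x, y, bx, by, spec, calibrate_thresholds(values)


class TestStreamDetect:
    def test_flat_theta_at_mean_times_out(self, calibrated):
        x, y, bx, by, spec, prof = calibrated
        # thresholds far beyond anything the stream reaches
        wide = ThresholdProfile(mean=prof.mean, sd=10.0)
        out = stream_detect(x, y, bx, by, spec, wide, "high", timeout=10.0)
        assert out.cause == "timeout"
        assert out.trigger_time == 10.0

    def test_high_state_triggers_with_bounded_latency(self):
        spec_osc = tb.OscillatorSpec(sampling_rate=1000.0)
        ws = WindowSpec()
        hits = 0
        runs = 30
        lead_osc = tb.OscillatorSpec(sampling_rate=1000.0, theta_amp_private=0.0)
        for seed in range(runs):
            # 5 s with no theta coupling at all, then a sustained strongly
            # coupled high state: the first full-high window sits clearly
            # above threshold, so latency reflects window mechanics alone
            lead = tb.CoherenceStateTrack(("low",), (5.0,))
            high = tb.CoherenceStateTrack(("high",), (30.0,))
            lx, ly = tb.gen_coupled_lfp(lead_osc, lead_osc, lead, seed=seed)
            hx, hy = tb.gen_coupled_lfp(spec_osc, spec_osc, high, seed=seed, high_mix=3.5)
            x = tb.ContinuousSignal(np.concatenate([lx.samples, hx.samples]), 1000.0)
            y = tb.ContinuousSignal(np.concatenate([ly.samples, hy.samples]), 1000.0)
            bx, by = compute_baseline(x), compute_baseline(y)
            cal = tb.CoherenceStateTrack.alternating(20, 3.0, 3.0)
            cx, cy = tb.gen_coupled_lfp(spec_osc, spec_osc, cal, seed=1000 + seed)
            values = [
                e.theta_value
                for e in iter_epochs(cx, cy, compute_baseline(cx), compute_baseline(cy), ws)
                if e.clean
            ]
            prof = calibrate_thresholds(values)
            out = stream_detect(x, y, bx, by, ws, prof, "high", timeout=30.0)
            if out.cause == "threshold" and 5.0 <= out.trigger_time <= 5.0 + ws.window_len + ws.step:
                hits += 1
        assert hits >= 0.95 * runs - 1  # latency bound holds in ≥95% of runs

    def test_detector_monotonicity_in_threshold(self, calibrated):
        x, y, bx, by, spec, prof = calibrated
        t_lo = stream_detect(x, y, bx, by, spec, prof, "high", timeout=60.0)
        higher = ThresholdProfile(mean=prof.mean + 0.05, sd=prof.sd)
        t_hi = stream_detect(x, y, bx, by, spec, higher, "high", timeout=60.0)
        assert t_hi.trigger_time >= t_lo.trigger_time

    def test_saturated_crossing_cannot_trigger(self, calibrated):
        x, y, bx, by, spec, prof = calibrated
        # saturate the first 8 s so early crossings are gated out
        x2 = x.copy()
        x2.samples[: int(8 * x.sampling_rate)] = 50.0 * bx.sd
        out_gated = stream_detect(x2, y, bx, by, spec, prof, "high", timeout=60.0)
        if out_gated.cause == "threshold":
            assert out_gated.trigger_time > 8.0 - spec.window_len

    def test_stream_shorter_than_window_rejected(self, calibrated, rng):
        x, y, bx, by, spec, prof = calibrated
        short = tb.ContinuousSignal(rng.standard_normal(100), x.sampling_rate)
        with pytest.raises(ValueError, match="shorter than one window"):
            stream_detect(short, short, bx, by, spec, prof, "high", 30.0)


class TestEndToEndDiscrimination:
    def test_high_states_dominate_low_states(self, coupled_pair):
        from scipy.stats import mannwhitneyu

        x, y, states, bx, by = coupled_pair
        mask = states.state_mask(x.n_samples, x.sampling_rate)
        hi, lo = [], []
        for e in iter_epochs(x, y, bx, by):
            if not e.clean:
                continue
            i0 = int(e.t_start * x.sampling_rate)
            i1 = i0 + int(1.25 * x.sampling_rate)
            frac = mask[i0:i1].mean()
            if frac == 1.0:
                hi.append(e.theta_value)
            elif frac == 0.0:
                lo.append(e.theta_value)
        assert len(hi) > 50 and len(lo) > 50
        stat, p = mannwhitneyu(hi, lo, alternative="greater")
        assert p < 1e-6


@settings(max_examples=50, deadline=None)
@given(st.floats(0.05, 0.95), st.floats(0.01, 0.3))
def test_threshold_profile_invariants(mean, sd):
    prof = ThresholdProfile(mean=mean, sd=sd)
    assert prof.low < prof.mean < prof.high
    assert prof.high - prof.low == pytest.approx(2 * sd)
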