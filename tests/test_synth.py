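import numpy as np
import pytest
from scipy import stats as sstats

import thetabmi as tb
from thetabmi.coherence import WindowSpec, compute_baseline, iter_epochs
from thetabmi.spike_lfp import rayleigh, spike_phases
from thetabmi.synth import (
    HIGH_STATE_MIX,
    ArtifactTruth,
    gen_locked_spikes,
    gen_trajectory,
    inject_artifacts,
)

FS = 1000.0


def clean_theta_values(x, y, spec=None):
    bx, by = compute_baseline(x), compute_baseline(y)
    return np.array([e.theta_value for e in iter_epochs(x, y, bx, by, spec) if e.clean])


class TestGenCoupledLfp:
    def test_deterministic_given_seed(self):
        spec = tb.OscillatorSpec(sampling_rate=FS)
        states = tb.CoherenceStateTrack.alternating(4, 2.0, 2.0)
        a1, b1 = tb.gen_coupled_lfp(spec, spec, states, seed=5)
        a2, b2 = tb.gen_coupled_lfp(spec, spec, states, seed=5)
        assert np.array_equal(a1.samples, a2.samples)
        assert np.array_equal(b1.samples, b2.samples)

    def test_rate_mismatch_rejected(self):
        s1 = tb.OscillatorSpec(sampling_rate=1000)
        s2 = tb.OscillatorSpec(sampling_rate=2000)
        states = tb.CoherenceStateTrack(("high",), (2.0,))
        with pytest.raises(ValueError, match="mismatch"):
            tb.gen_coupled_lfp(s1, s2, states, seed=0)

    def test_zero_coupling_matches_independent_noise(self):
        """With zero shared amplitude the long-run theta coherence equals
        that of independently generated channels with the same spectrum."""
        spec = tb.OscillatorSpec(sampling_rate=FS, theta_amp_shared=0.0)
        states = tb.CoherenceStateTrack(("high",), (150.0,))
        x, y = tb.gen_coupled_lfp(spec, spec, states, seed=11)
        v_zero = clean_theta_values(x, y)
        # independent-noise oracle: channels from two separate seeds
        x1, _ = tb.gen_coupled_lfp(spec, spec, states, seed=12)
        _, y2 = tb.gen_coupled_lfp(spec, spec, states, seed=13)
        v_ind = clean_theta_values(x1, y2)
        _, p = sstats.mannwhitneyu(v_zero, v_ind)
        assert p > 0.01  # statistically indistinguishable

    def test_identical_shared_drive_gives_unit_coherence(self):
        spec = tb.OscillatorSpec(
            sampling_rate=FS, theta_amp_private=0.0, noise_sd=0.0, delta_amp=0.0
        )
        states = tb.CoherenceStateTrack(("high",), (30.0,))
        x, y = tb.gen_coupled_lfp(spec, spec, states, seed=3)
        bx, by = compute_baseline(x), compute_baseline(y)
        for e in iter_epochs(x, y, bx, by):
            assert np.allclose(e.coherence, 1.0, atol=1e-6)

    def test_frozen_mix_hits_target_coherence_at_8hz(self):
        """The frozen high-state mixing weight yields 0.7 ± 0.05 MSC at 8 Hz
        over ≥100 clean windows at the nominal 2 kHz rate."""
        spec = tb.OscillatorSpec()  # 2 kHz defaults
        states = tb.CoherenceStateTrack(("high",), (60.0,))
        ws = WindowSpec()
        i8 = int(np.argmin(np.abs(ws.freq_grid - 8.0)))
        vals = []
        for seed in range(3):
            x, y = tb.gen_coupled_lfp(spec, spec, states, seed=seed, high_mix=HIGH_STATE_MIX)
            bx, by = compute_baseline(x), compute_baseline(y)
            vals += [e.coherence[i8] for e in iter_epochs(x, y, bx, by) if e.clean]
        assert len(vals) >= 100
        assert np.mean(vals) == pytest.approx(0.7, abs=0.05)

    def test_coherence_controllability(self, coupled_pair):
        """High-state theta coherence exceeds low-state coherence (two-sample
        test, p < 0.01) for the default mixing margin."""
        x, y, states, bx, by = coupled_pair
        mask = states.state_mask(x.n_samples, x.sampling_rate)
        hi, lo = [], []
        for e in iter_epochs(x, y, bx, by):
            i0 = int(e.t_start * x.sampling_rate)
            frac = mask[i0 : i0 + int(1.25 * x.sampling_rate)].mean()
            (hi if frac == 1.0 else lo if frac == 0.0 else []).append(e.theta_value)
        assert len(hi) >= 100 and len(lo) >= 100
        _, p = sstats.mannwhitneyu(hi, lo, alternative="greater")
        assert p < 0.01


@pytest.fixture(scope="module")
def base():
    spec = tb.OscillatorSpec(sampling_rate=FS)
    states = tb.CoherenceStateTrack(("high",), (60.0,))
    x, _ = tb.gen_coupled_lfp(spec, spec, states, seed=21)
    return x


class TestInjectArtifacts:
    def test_zero_rates_are_identity(self, base):
        out, truth = inject_artifacts(base, 0.0, 2000.0, 0.0, seed=0)
        assert np.array_equal(out.samples, base.samples)
        assert truth.intervals == []

    def test_saturation_fraction_injected(self, base):
        out, truth = inject_artifacts(base, 0.02, 2000.0, 0.0, seed=1)
        frac = np.mean(np.abs(out.samples) == 2000.0)
        assert frac == pytest.approx(0.02, rel=0.3)
        assert all(k == "saturation" for _, _, k in truth.intervals)

    def test_saturated_window_fails_downstream_check(self, base):
        """A window with 2% of its samples saturated is rejected by the gate
        (>1% rule), while an uncorrupted window passes."""
        fs = base.sampling_rate
        n_win = int(1.25 * fs)
        window = tb.ContinuousSignal(base.samples[:n_win].copy(), fs)
        out, truth = inject_artifacts(window, 0.02, 6000.0, 0.0, seed=2)
        bx = compute_baseline(base)
        epochs = list(iter_epochs(out, window, bx, bx))
        assert len(epochs) == 1
        assert epochs[0].verdict == "saturated"
        clean = list(iter_epochs(window, window, bx, bx))
        assert clean[0].verdict != "saturated"

    def test_delta_burst_rejected_downstream(self, base):
        """A coherent delta burst spanning a window drives delta coherence
        above theta coherence there."""
        spec = tb.OscillatorSpec(sampling_rate=FS)
        states = tb.CoherenceStateTrack(("high",), (60.0,))
        x, y = tb.gen_coupled_lfp(spec, spec, states, seed=22)
        amp = 3.0 * float(np.std(x.samples))
        xa, truth = inject_artifacts(x, 0.0, 2000.0, 4.0, seed=7, burst_amp=amp)
        ya, _ = inject_artifacts(y, 0.0, 2000.0, 4.0, seed=7, burst_amp=amp)
        bx, by = compute_baseline(x), compute_baseline(y)
        covered = rejected = 0
        for e in iter_epochs(xa, ya, bx, by):
            if truth.covering(e.t_start, e.t_start + 1.25, "delta_burst"):
                covered += 1
                rejected += e.verdict != "clean"
        assert covered >= 3
        assert rejected / covered >= 0.95

    def test_invalid_saturation_level(self, base):
        with pytest.raises(ValueError):
            inject_artifacts(base, 0.1, -5.0, 0.0, seed=0)

    def test_ground_truth_intervals_cover_modified_samples(self, base):
        out, truth = inject_artifacts(base, 0.01, 2000.0, 2.0, seed=3)
        changed = np.nonzero(out.samples != base.samples)[0] / FS
        for t in changed:
            assert truth.overlaps(t - 1e-9, t + 1e-3 + 1e-9)


class TestGenLockedSpikes:
    def test_uniform_kappa_is_rayleigh_null(self, theta_lfp):
        nonsig = 0
        runs = 40
        for seed in range(runs):
            spikes = gen_locked_spikes(theta_lfp, (4, 12), 0.0, 0.0, rate=5.0, seed=seed)
            ps = spike_phases(theta_lfp, spikes)
            r = rayleigh(ps)
            nonsig += r is not None and r.rayleigh_p > 0.05
        assert nonsig >= 0.9 * runs

    def test_high_kappa_gives_high_mrl(self, theta_lfp):
        spikes = gen_locked_spikes(theta_lfp, (4, 12), 5.0, 0.0, rate=10.0, seed=1)
        ps = spike_phases(theta_lfp, spikes)
        assert ps.n >= 500
        assert ps.resultant_length() > 0.8  # I1(5)/I0(5) ≈ 0.89

    def test_preferred_phase_recovered(self, theta_lfp):
        spikes = gen_locked_spikes(theta_lfp, (4, 12), 5.0, np.pi, rate=10.0, seed=2)
        ps = spike_phases(theta_lfp, spikes)
        # circular distance to π
        d = np.angle(np.exp(1j * (ps.circular_mean() - np.pi)))
        assert abs(d) < 0.15

    def test_phase_law_matches_von_mises(self, theta_lfp):
        """Empirical phases at κ=2 pass a von Mises goodness-of-fit test."""
        spikes = gen_locked_spikes(theta_lfp, (4, 12), 2.0, 0.5, rate=25.0, seed=3)
        ps = spike_phases(theta_lfp, spikes)
        assert ps.n >= 2000
        kappa_hat, loc, _ = sstats.vonmises.fit(ps.phases, fscale=1)
        _, p = sstats.kstest(ps.phases, sstats.vonmises(kappa=2.0, loc=0.5).cdf)
        assert p > 0.01

    def test_band_outside_nyquist_rejected(self, theta_lfp):
        with pytest.raises(ValueError, match="Nyquist"):
            gen_locked_spikes(theta_lfp, (4, 600), 1.0, 0.0, rate=5.0, seed=0)


class TestGenTrajectory:
    def test_straight_length_exact(self):
        tr = gen_trajectory("straight", 100.0, 200, 0.0, seed=0)
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        assert np.sum(steps) == pytest.approx(100.0, abs=1e-9)

    def test_tortuous_has_heading_reversals(self):
        tr = gen_trajectory("tortuous", 100.0, 240, 0.0, seed=0)
        headings = np.arctan2(np.diff(tr.y), np.diff(tr.x))
        turns = np.diff(np.unwrap(headings))
        assert (turns > 0).any() and (turns < 0).any()

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            gen_trajectory("straight", -1.0, 10, 0.0, seed=0)

    def test_determinism(self):
        a = gen_trajectory("tortuous", 50.0, 100, 0.5, seed=9)
        b = gen_trajectory("tortuous", 50.0, 100, 0.5, seed=9)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestGenSession:
    def test_byte_identical_given_seed(self):
        a = tb.gen_session("delayed_alternation", seed=4, n_blocks=1,
                           sampling_rate=250.0, calibration_s=40.0)
        b = tb.gen_session("delayed_alternation", seed=4, n_blocks=1,
                           sampling_rate=250.0, calibration_s=40.0)
        assert np.array_equal(a.lfp_x.samples, b.lfp_x.samples)
        assert a.trials.equals(b.trials)
        assert a.events.records["time"].equals(b.events.records["time"])

    def test_four_blocks_of_ten(self):
        bundle = tb.gen_session("delayed_alternation", seed=6, n_blocks=4,
                                sampling_rate=250.0, calibration_s=40.0)
        assert len(bundle.records) == 40
        assert np.array_equal(np.sort(bundle.trials["block"].unique()), [0, 1, 2, 3])
        assert (bundle.trials["block"].value_counts() == 10).all()

    def test_no_high_states_means_no_high_triggers(self):
        ref = tb.gen_session("delayed_alternation", seed=8, n_blocks=1,
                             sampling_rate=250.0, calibration_s=60.0)
        # a session with no coherent theta episodes at all, screened against
        # thresholds calibrated on a normal reference session
        flat = tb.OscillatorSpec(sampling_rate=250.0, theta_amp_private=0.0)
        bundle = tb.gen_session(
            "delayed_alternation", seed=8, n_blocks=2, sampling_rate=250.0,
            calibration_s=40.0, high_dwell=0.0, thresholds=ref.thresholds,
            osc_spec=flat,
        )
        high = bundle.trials[bundle.trials["type"] == "high"]
        assert len(high) == 2
        assert (high["trigger_cause"] == "timeout").all()
        # the substitution rule converted the pending yoked partners
        assert (bundle.trials["type"] != "yoked_high").all()
        assert bundle.trials["was_yoked"].sum() == 2

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ValueError, match="unknown protocol"):
            tb.gen_session("serial_reaction", seed=0)
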