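"""Synthetic dual-site LFP, spike, trajectory and session generators.

Everything downstream is exercised on data from this module, so the
generators reproduce the statistical structure the analyses assume rather
than any biophysics: theta oscillators are narrowband-filtered noise plus a
weak sinusoidal drive (pure tones would give degenerate unit coherence),
inter-site coupling is a shared theta component whose mixing weight follows
a high/low state track, movement artifacts are amplifier-saturation runs and
large 1–4 Hz transients injected identically into both channels, spikes are
phase-locked to one site's filtered theta by a von Mises law, and position
tracks are straight or tortuous constant-speed paths.

Amplitudes follow a nominal µV scale (theta ~200 µV, saturation ±2000 µV)
so absolute-voltage cutoffs downstream are meaningful.  Every generator is
deterministic given its seed, and corrupted signals are always returned
together with ground-truth artifact intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from . import scheduler as sched
from .coherence import (
    BaselineStats,
    ThresholdProfile,
    WindowSpec,
    calibrate_thresholds,
    compute_baseline,
    iter_epochs,
    stream_detect,
)
from .io import BehaviorTrack, ContinuousSignal, EventLog, SpikeTrain

#: Mixing weight of the shared theta component during "high" states that
#: yields ~0.7 magnitude-squared coherence at 8 Hz with the default
#: oscillator amplitudes at the nominal 2 kHz rate (calibrated once by a
#: brute-force sweep against the package's own estimator, then frozen).
HIGH_STATE_MIX = 1.7

#: Strongly synchronized, theta-dominant regime in which the artifact gate
#: should never fire on uncorrupted windows: coherence ≈ 0.99 in theta,
#: independent delta noise masking spectral leakage, and constant-envelope
#: (phase-noise) oscillators whose bounded amplitude keeps every sample well
#: inside 4 baseline SDs — Gaussian narrowband envelopes occasionally swell
#: past 4σ for more than 1% of a window, which is a genuine rejection, not a
#: clean one.  Used for clean-window gating validation.
CLEAN_THETA_SPEC = dict(
    theta_amp_shared=1200.0,
    theta_amp_private=15.0,
    noise_sd=15.0,
    delta_amp=300.0,
    constant_envelope=True,
)


@dataclass(frozen=True)
class OscillatorSpec:
    """One site's oscillator: theta drive, private/shared amplitudes, noise."""

    theta_freq: float = 8.0
    theta_amp_shared: float = 200.0
    theta_amp_private: float = 200.0
    noise_sd: float = 120.0
    delta_amp: float = 40.0
    sampling_rate: float = 2000.0
    #: constant-envelope oscillators carry all their randomness in the phase
    #: (bounded amplitude, no 4σ excursions); Gaussian envelopes are the default
    constant_envelope: bool = False

    def __post_init__(self) -> None:
        for name in ("theta_amp_shared", "theta_amp_private", "delta_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sampling_rate <= 2 * max(self.theta_freq + 2.0, 4.0):
            raise ValueError("sampling_rate must exceed twice the highest generated frequency")


@dataclass(frozen=True)
class CoherenceStateTrack:
    """Alternating high/low coupling states with per-state dwell times (s)."""

    state_labels: tuple[str, ...]
    dwell_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.state_labels) != len(self.dwell_times):
            raise ValueError("labels and dwell_times must have equal lengths")
        if any(d <= 0 for d in self.dwell_times):
            raise ValueError("dwell_times must be positive")
        if set(self.state_labels) - {"high", "low"}:
            raise ValueError("state labels must be 'high' or 'low'")

    @property
    def duration(self) -> float:
        return float(sum(self.dwell_times))

    @classmethod
    def alternating(
        cls, n_states: int, high_dwell: float, low_dwell: float, start: str = "high"
    ) -> "CoherenceStateTrack":
        labels, dwells = [], []
        cur = start
        for _ in range(n_states):
            labels.append(cur)
            dwells.append(high_dwell if cur == "high" else low_dwell)
            cur = "low" if cur == "high" else "high"
        return cls(tuple(labels), tuple(dwells))

    def mixing_weight(self, n_samples: int, fs: float, high_mix: float, low_mix: float) -> np.ndarray:
        w = np.empty(n_samples)
        i = 0
        for label, dwell in zip(self.state_labels, self.dwell_times):
            n = int(round(dwell * fs))
            w[i : i + n] = high_mix if label == "high" else low_mix
            i += n
        w[i:] = w[i - 1] if i > 0 else low_mix
        return w

    def state_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Boolean per-sample mask, True inside 'high' states."""
        return self.mixing_weight(n_samples, fs, 1.0, 0.0) > 0.5


def _narrowband_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    lo: float,
    hi: float,
    constant_envelope: bool = False,
) -> np.ndarray:
    """Unit-variance noise band-filtered to [lo, hi] Hz (zero-phase).

    With ``constant_envelope`` the Hilbert envelope is divided out, leaving a
    bounded phase-noise oscillator (|x| ≤ √2 after normalization)."""
    white = rng.standard_normal(n)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    if constant_envelope:
        env = np.abs(sps.hilbert(x))
        x = x / np.maximum(env, 1e-12 * np.max(env))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def gen_coupled_lfp(
    spec_a: OscillatorSpec,
    spec_b: OscillatorSpec,
    states: CoherenceStateTrack,
    seed: int,
    high_mix: float = HIGH_STATE_MIX,
    low_mix: float = 0.0,
) -> tuple[ContinuousSignal, ContinuousSignal]:
    """Two theta oscillators sharing a state-gated common component.

    Each site is private narrowband theta + white noise + a little delta,
    plus ``mix(t) · theta_amp_shared`` of a common narrowband theta process,
    where ``mix(t)`` is ``high_mix`` inside high states and ``low_mix``
    inside low states.  Theta-band coherence therefore tracks the state
    sequence; with both amplitudes zero the two channels are independent.
    """
    if spec_a.sampling_rate != spec_b.sampling_rate:
        raise ValueError("sampling_rate mismatch between specs")
    fs = spec_a.sampling_rate
    n = int(round(states.duration * fs))
    if n <= 0:
        raise ValueError("non-positive duration")
    rng = np.random.default_rng(seed)
    f0 = 0.5 * (spec_a.theta_freq + spec_b.theta_freq)
    stab = spec_a.constant_envelope
    shared = _narrowband_noise(rng, n, fs, f0 - 1.5, f0 + 1.5, constant_envelope=stab)
    mix = states.mixing_weight(n, fs, high_mix, low_mix)
    out = []
    for spec in (spec_a, spec_b):
        # a narrowband stochastic oscillator, not a pure tone: tones at a
        # shared frequency would carry a fixed relative phase and inject
        # artifactual coherence even with zero coupling
        private = _narrowband_noise(
            rng, n, fs, spec.theta_freq - 1.5, spec.theta_freq + 1.5,
            constant_envelope=spec.constant_envelope,
        )
        delta = (
            _narrowband_noise(rng, n, fs, 1.0, 4.0, constant_envelope=spec.constant_envelope)
            if spec.delta_amp > 0
            else 0.0
        )
        x = (
            mix * spec.theta_amp_shared * shared
            + spec.theta_amp_private * private
            + spec.delta_amp * delta
            + spec.noise_sd * rng.standard_normal(n)
        )
        out.append(ContinuousSignal(x, fs, region="other"))
    out[0].region = "mPFC"
    out[1].region = "HPC"
    return out[0], out[1]


@dataclass
class ArtifactTruth:
    """Ground-truth artifact intervals: (t_start, t_end, kind) in seconds."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def covering(self, t0: float, t1: float, kind: str | None = None) -> bool:
        """True if some interval of the given kind covers [t0, t1] entirely."""
        for a, b, k in self.intervals:
            if (kind is None or k == kind) and a <= t0 and b >= t1:
                return True
        return False

    def overlaps(self, t0: float, t1: float) -> bool:
        return any(a < t1 and b > t0 for a, b, _ in self.intervals)


def inject_artifacts(
    signal: ContinuousSignal,
    saturation_fraction: float,
    saturation_level: float,
    delta_burst_rate: float,
    seed: int,
    saturation_run: float = 0.05,
    burst_duration: float = 1.5,
    burst_amp: float | None = None,
) -> tuple[ContinuousSignal, ArtifactTruth]:
    """Corrupt a copy of ``signal`` with clipping runs and delta transients.

    Saturation: contiguous runs of ``saturation_run`` seconds are clipped at
    ±``saturation_level`` until the requested fraction of samples is
    saturated.  Delta bursts: ``delta_burst_rate`` events per minute, each a
    ``burst_duration`` s transient of dominant 1–4 Hz energy (amplitude
    ``burst_amp``, default 3× the signal SD).  Injecting with the same seed
    into two channels of a pair produces time-aligned, coherent artifacts,
    as movement artifacts are in vivo.
    """
    if not 0 <= saturation_fraction <= 1:
        raise ValueError("saturation_fraction must lie in [0, 1]")
    if saturation_level <= 0:
        raise ValueError("saturation_level must be positive")
    rng = np.random.default_rng(seed)
    out = signal.copy()
    truth = ArtifactTruth()
    fs = signal.sampling_rate
    n = signal.n_samples
    if saturation_fraction > 0:
        run = max(1, int(round(saturation_run * fs)))
        target = int(round(saturation_fraction * n))
        mask = np.zeros(n, dtype=bool)
        while mask.sum() < target:
            start = int(rng.integers(0, max(1, n - run)))
            length = min(run, target - int(mask.sum()) + run // 2, n - start)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.samples[start : start + length] = sign * saturation_level
            mask[start : start + length] = True
            truth.intervals.append(
                (signal.start_time + start / fs, signal.start_time + (start + length) / fs, "saturation")
            )
    if delta_burst_rate > 0:
        n_bursts = int(round(delta_burst_rate * signal.duration / 60.0))
        amp = burst_amp if burst_amp is not None else 3.0 * float(np.std(signal.samples))
        n_burst = int(round(burst_duration * fs))
        for _ in range(n_bursts):
            start = int(rng.integers(0, max(1, n - n_burst)))
            t = np.arange(n_burst) / fs
            f_burst = rng.uniform(1.5, 3.5)
            phase = rng.uniform(0, 2 * np.pi)
            envelope = np.hanning(n_burst)
            out.samples[start : start + n_burst] += amp * envelope * np.sin(
                2 * np.pi * f_burst * t + phase
            )
            truth.intervals.append(
                (signal.start_time + start / fs, signal.start_time + (start + n_burst) / fs, "delta_burst")
            )
    return out, truth


def gen_locked_spikes(
    lfp: ContinuousSignal,
    band: tuple[float, float],
    kappa: float,
    preferred_phase: float,
    rate: float,
    seed: int,
    unit_id: str = "unit0",
) -> SpikeTrain:
    """Spike train whose phases against the band-filtered LFP are von Mises.

    Phases are drawn directly from von Mises(``preferred_phase``, ``kappa``)
    (uniform when ``kappa`` = 0) and mapped to spike times by inverting the
    unwrapped Hilbert phase of the band-filtered signal, so the law holds
    against the same phase estimate the analyses use.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if rate <= 0:
        raise ValueError("rate must be positive")
    lo, hi = band
    if hi >= lfp.sampling_rate / 2:
        raise ValueError("band outside Nyquist range")
    rng = np.random.default_rng(seed)
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=lfp.sampling_rate, output="sos")
    analytic = sps.hilbert(sps.sosfiltfilt(sos, lfp.samples))
    wrapped = np.angle(analytic)
    phase = np.unwrap(wrapped)
    # enforce monotonicity so the phase→time map is invertible; flattened
    # stretches mark phase slips where placement would be unreliable
    phase_mono = np.maximum.accumulate(phase)
    t = lfp.start_time + np.arange(lfp.n_samples) / lfp.sampling_rate
    n_spikes = rng.poisson(rate * lfp.duration)
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, n_spikes)
    else:
        theta = rng.vonmises(preferred_phase, kappa, n_spikes)
    lo_cycle = int(np.ceil(phase_mono[0] / (2 * np.pi))) + 1
    hi_cycle = int(np.floor(phase_mono[-1] / (2 * np.pi))) - 1
    if hi_cycle <= lo_cycle:
        raise ValueError("LFP too short to place spikes")
    cycles = rng.integers(lo_cycle, hi_cycle, n_spikes)
    targets = 2 * np.pi * cycles + theta
    # snap each spike to the sample whose measured phase is nearest the
    # drawn phase, and drop placements landing on slip regions so the
    # measured distribution follows the requested law
    idx = np.clip(np.searchsorted(phase_mono, targets), 1, lfp.n_samples - 1)
    idx = np.where(
        np.abs(phase_mono[idx - 1] - targets) < np.abs(phase_mono[idx] - targets),
        idx - 1,
        idx,
    )
    err = np.abs(np.angle(np.exp(1j * (wrapped[idx] - theta))))
    keep = err < 0.1
    times = t[idx[keep]]
    return SpikeTrain(np.sort(times), unit_id=unit_id, region=lfp.region)


def gen_trajectory(
    kind: Literal["straight", "tortuous"],
    length: float,
    n_points: int,
    noise_sd: float,
    seed: int,
    dt: float = 1.0 / 30.0,
    reversal_every: int = 12,
    turn_rate: float = np.pi / 8,
) -> BehaviorTrack:
    """Constant-speed path of total length ``length``: straight heading, or a
    zig-zag with repeated heading reversals (for high IdPhi)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    step = length / (n_points - 1)
    heading0 = rng.uniform(0, 2 * np.pi)
    if kind == "straight":
        headings = np.full(n_points - 1, heading0)
    elif kind == "tortuous":
        sign = np.where((np.arange(n_points - 1) // reversal_every) % 2 == 0, 1.0, -1.0)
        headings = heading0 + np.cumsum(sign * turn_rate)
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    dx = step * np.cos(headings)
    dy = step * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, n_points)
        y = y + rng.normal(0, noise_sd, n_points)
    t = np.arange(n_points) * dt
    return BehaviorTrack(x, y, t)


# ---------------------------------------------------------------------------
# End-to-end session generation


@dataclass
class SessionBundle:
    """Everything one simulated session produced."""

    lfp_x: ContinuousSignal
    lfp_y: ContinuousSignal
    states: CoherenceStateTrack
    events: EventLog
    trials: "object"  # pandas DataFrame of trial records
    records: list
    thresholds: ThresholdProfile
    baseline_x: BaselineStats
    baseline_y: BaselineStats
    protocol: sched.ProtocolSpec


class _StreamingDetector:
    """Session-clock detector: runs the real streaming pipeline on the
    simulated LFP pair starting at a moving cursor."""

    def __init__(self, bundle_parts, spec: WindowSpec):
        (self.x, self.y, self.bx, self.by, self.thresholds) = bundle_parts
        self.spec = spec
        self.cursor = 0.0

    def __call__(self, mode: str, timeout: float) -> tuple[float, str]:
        fs = self.x.sampling_rate
        i0 = int(round(self.cursor * fs))
        n_need = int(round((timeout + self.spec.window_len) * fs))
        i1 = min(self.x.n_samples, i0 + n_need)
        if i1 - i0 < self.spec.window_samples(fs):
            return timeout, "timeout"
        seg_x = ContinuousSignal(self.x.samples[i0:i1], fs, self.x.region)
        seg_y = ContinuousSignal(self.y.samples[i0:i1], fs, self.y.region)
        outcome = stream_detect(
            seg_x, seg_y, self.bx, self.by, self.spec, self.thresholds, mode, timeout
        )
        return outcome.trigger_time, outcome.cause


def gen_session(
    protocol: sched.ProtocolSpec | str,
    seed: int,
    n_blocks: int = 4,
    spec: WindowSpec | None = None,
    sampling_rate: float = 2000.0,
    high_dwell: float = 2.5,
    low_dwell: float = 4.0,
    calibration_s: float = 120.0,
    run_time: float = 6.0,
    p_correct: dict[str, float] | None = None,
    thresholds: ThresholdProfile | None = None,
    osc_spec: OscillatorSpec | None = None,
) -> SessionBundle:
    """Simulate a full closed-loop session end to end.

    Generates a coupled LFP pair with alternating coherence states, computes
    baselines and per-subject thresholds from an initial calibration stretch,
    then runs the block scheduler against the real streaming detector over
    the remaining signal, emitting an event log and per-trial ground truth.
    """
    if isinstance(protocol, str):
        protocol = sched.ProtocolSpec.by_name(protocol)
    spec = spec or WindowSpec()
    rng = np.random.default_rng(seed)
    n_trials = n_blocks * protocol.block_size
    session_s = calibration_s + n_trials * (protocol.timeout + run_time) + 30.0
    if high_dwell <= 0:
        # no high states at all: every high-mode detector trial must time out
        n_states = int(np.ceil(session_s / low_dwell)) + 2
        states = CoherenceStateTrack(("low",) * n_states, (low_dwell,) * n_states)
    else:
        n_states = int(np.ceil(session_s / min(high_dwell, low_dwell))) + 2
        states = CoherenceStateTrack.alternating(n_states, high_dwell, low_dwell)
    spec_osc = osc_spec or OscillatorSpec(sampling_rate=sampling_rate)
    x, y = gen_coupled_lfp(spec_osc, spec_osc, states, seed=int(rng.integers(2**31)))
    bx, by = compute_baseline(x), compute_baseline(y)

    # calibration: distribution of clean theta values over the first stretch
    if thresholds is None:
        cal_values = [
            ep.theta_value
            for ep in iter_epochs(x, y, bx, by, spec, t_stop=calibration_s)
            if ep.clean
        ]
        thresholds = calibrate_thresholds(cal_values, subject_id=f"sim{seed}")

    detector = _StreamingDetector((x, y, bx, by, thresholds), spec)
    detector.cursor = calibration_s

    events = EventLog()
    events.append(0.0, "session_start")
    records = []
    state = sched.SessionState()
    prev_turn = None
    p = dict(sched.DEFAULT_P_CORRECT if p_correct is None else p_correct)
    for b in range(n_blocks):
        state.block_index = b
        state.plan = [{"type": t, "was_yoked": False} for t in sched.plan_block(protocol, rng)]
        while state.plan:
            entry = state.plan.pop(0)
            t_start = detector.cursor
            rec = sched.run_trial(entry, protocol, detector, state, rng)
            rec.outcome, rec.turn = sched._default_outcome(rec, prev_turn, rng, p, protocol)
            prev_turn = rec.turn
            records.append(rec)
            events.append(t_start, "trial_start", trial=rec.index, type=rec.type)
            t_door = t_start + rec.delay
            events.append(t_door, "door_open", trial=rec.index)
            t_entry = t_door + 0.6 * run_time
            events.append(t_entry, "choice_entry", trial=rec.index)
            events.append(t_entry + 0.15 * run_time, "choice_exit", trial=rec.index)
            if rec.outcome == "correct":
                events.append(t_entry + 0.2 * run_time, "reward", trial=rec.index)
            detector.cursor = t_door + run_time
    return SessionBundle(
        lfp_x=x,
        lfp_y=y,
        states=states,
        events=events,
        trials=sched.records_to_frame(records),
        records=records,
        thresholds=thresholds,
        baseline_x=bx,
        baseline_y=by,
        protocol=protocol,
    )
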