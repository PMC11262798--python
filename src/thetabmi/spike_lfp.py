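"""Spike-phase entrainment and spike-field coherence across coherence states.

Spike phases are read off the 4–12 Hz Butterworth-filtered (3rd order,
zero-phase) LFP via the Hilbert transform; a spike only contributes when the
instantaneous theta envelope is at least twice the delta envelope at that
moment, so delta-dominated (movement) stretches never enter the phase pool.
Entrainment is quantified by Rayleigh's test of non-uniformity and by a
bootstrapped mean resultant length (MRL: 50 spikes per draw, 1000 draws,
averaged) that removes the spike-count dependence of the raw resultant.
Spike-field coherence (SFC) convolves the LFP with six-cycle complex Morlet
wavelets on a 1–20 Hz grid (0.5 Hz spacing) and takes, per frequency, the
length of the average unit phasor over spikes — a phase-only statistic,
invariant to LFP amplitude.

Units are included only with more than 50 gated spike phases in both the
high- and low-coherence state (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from pingouin import circ_rayleigh
from scipy import signal as sps

from .io import ContinuousSignal, SpikeTrain
from .spectral import norm_diff

SFC_FREQS = np.arange(1.0, 20.0 + 1e-9, 0.5)


# ---------------------------------------------------------------------------
# Epoch cleaning for spike analyses


@dataclass
class CleanedEpochs:
    """Artifact-screened epochs concatenated into one timeline.

    ``intervals`` are the surviving (t0, t1) source intervals in order;
    ``signals`` maps region to the concatenated clean LFP; ``offsets`` give
    each surviving interval's start time in the concatenated timeline.
    """

    intervals: list[tuple[float, float]]
    removed: list[tuple[float, float]]
    signals: dict[str, ContinuousSignal]
    offsets: np.ndarray

    def map_spikes(self, train: SpikeTrain) -> SpikeTrain:
        """Map spike timestamps into the concatenated timeline; spikes in
        removed intervals vanish, duplicates are filtered."""
        mapped = []
        for (t0, t1), off in zip(self.intervals, self.offsets):
            sel = train.timestamps[(train.timestamps >= t0) & (train.timestamps < t1)]
            mapped.append(sel - t0 + off)
        ts = np.concatenate(mapped) if mapped else np.array([])
        return SpikeTrain(np.unique(ts), unit_id=train.unit_id, region=train.region)


def clean_epochs_for_spikes(
    signals: Mapping[str, ContinuousSignal],
    intervals: Sequence[tuple[float, float]],
    sd_cutoff: float | Mapping[str, float] = 4.0,
    abs_limit: float = 3500.0,
    max_fraction: float = 0.01,
    abs_limit_regions: tuple[str, ...] = ("mPFC", "VMT"),
) -> CleanedEpochs:
    """Screen candidate epochs for artifacts and concatenate the survivors.

    Per region, a z-score cutoff (``sd_cutoff`` SDs, computed on the
    concatenation of all candidate epochs for that region) flags extreme
    voltage samples; an epoch is removed if more than ``max_fraction`` of
    any region's samples exceed the cutoff, or if any sample in an
    ``abs_limit_regions`` signal exceeds ``abs_limit`` µV in magnitude.
    """
    intervals = sorted(intervals)
    for (a0, a1), (b0, b1) in zip(intervals[:-1], intervals[1:]):
        if b0 < a1:
            raise ValueError("overlapping epochs: spike mapping would be ambiguous")
    cuts = (
        dict(sd_cutoff)
        if isinstance(sd_cutoff, Mapping)
        else {r: float(sd_cutoff) for r in signals}
    )
    # per-region absolute voltage threshold referenced from the concatenated z-score
    slices: dict[str, list[np.ndarray]] = {r: [] for r in signals}
    for region, sig in signals.items():
        for t0, t1 in intervals:
            i0, i1 = sig.time_to_index(t0), sig.time_to_index(t1)
            slices[region].append(sig.samples[max(i0, 0) : i1])
    stats = {}
    for region in signals:
        concat = np.concatenate(slices[region])
        stats[region] = (concat.mean(), concat.std())

    kept, removed = [], []
    for j, (t0, t1) in enumerate(intervals):
        bad = False
        for region in signals:
            seg = slices[region][j]
            mu, sd = stats[region]
            if sd > 0 and np.mean(np.abs(seg - mu) > cuts[region] * sd) > max_fraction:
                bad = True
                break
            if region in abs_limit_regions and np.any(np.abs(seg) > abs_limit):
                bad = True
                break
        (removed if bad else kept).append((t0, t1))
    if not kept:
        raise ValueError("no epochs survive artifact screening")
    offsets = np.concatenate([[0.0], np.cumsum([t1 - t0 for t0, t1 in kept])[:-1]])
    out_signals = {}
    for region, sig in signals.items():
        parts = [
            sig.samples[sig.time_to_index(t0) : sig.time_to_index(t1)]
            for t0, t1 in kept
        ]
        out_signals[region] = ContinuousSignal(
            np.concatenate(parts), sig.sampling_rate, region=sig.region
        )
    return CleanedEpochs(intervals=kept, removed=removed, signals=out_signals, offsets=offsets)


# ---------------------------------------------------------------------------
# Spike phases


@dataclass
class SpikePhaseSet:
    """Gated spike phases (radians in (−π, π]) for one unit in one state."""

    phases: np.ndarray
    unit_id: str = "unit0"
    state: Literal["high", "low", "all"] = "all"

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)

    @property
    def n(self) -> int:
        return self.phases.size

    def resultant_length(self) -> float:
        if self.n == 0:
            return 0.0
        return float(np.abs(np.mean(np.exp(1j * self.phases))))

    def circular_mean(self) -> float:
        return float(np.angle(np.mean(np.exp(1j * self.phases))))


def _bandpass_phase_envelope(
    x: np.ndarray, fs: float, band: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    analytic = sps.hilbert(sps.sosfiltfilt(sos, x))
    return np.angle(analytic), np.abs(analytic)


def spike_phases(
    lfp: ContinuousSignal,
    spikes: SpikeTrain,
    theta_band: tuple[float, float] = (4.0, 12.0),
    delta_band: tuple[float, float] = (1.0, 4.0),
    gate_ratio: float = 2.0,
    gate: Literal["envelope", "rms"] = "envelope",
    rms_window: float = 0.5,
    unit_id: str | None = None,
    state: str = "all",
) -> SpikePhaseSet:
    """Theta phase of the LFP at each spike time, gated on theta dominance.

    A spike is included iff the instantaneous theta envelope is at least
    ``gate_ratio`` times the delta envelope at that time (``gate='rms'``
    swaps Hilbert envelopes for windowed RMS amplitudes).
    """
    if spikes.n_spikes == 0:
        raise ValueError("empty spike train")
    phase, theta_env = _bandpass_phase_envelope(lfp.samples, lfp.sampling_rate, theta_band)
    _, delta_env = _bandpass_phase_envelope(lfp.samples, lfp.sampling_rate, delta_band)
    if gate == "rms":
        n_w = max(1, int(round(rms_window * lfp.sampling_rate)))
        kernel = np.ones(n_w) / n_w
        theta_env = np.sqrt(np.convolve(theta_env**2, kernel, mode="same"))
        delta_env = np.sqrt(np.convolve(delta_env**2, kernel, mode="same"))
    idx = np.array([lfp.time_to_index(t) for t in spikes.timestamps])
    valid = (idx >= 0) & (idx < lfp.n_samples)
    idx = idx[valid]
    gate_ok = theta_env[idx] >= gate_ratio * delta_env[idx]
    return SpikePhaseSet(
        phases=phase[idx[gate_ok]],
        unit_id=unit_id or spikes.unit_id,
        state=state,
    )


# ---------------------------------------------------------------------------
# Entrainment statistics


@dataclass
class EntrainmentResult:
    rayleigh_z: float
    rayleigh_p: float
    mrl_boot: float
    n_spikes: int
    significant: bool


def rayleigh(phase_set: SpikePhaseSet, min_n: int = 50, alpha: float = 0.05):
    """Rayleigh test of circular non-uniformity: z = N·R̄² with the
    small-sample-corrected p-value.  Units with N ≤ ``min_n`` (strict
    inclusion: more than ``min_n`` phases required) are excluded — returns
    None rather than raising."""
    n = phase_set.n
    if n <= min_n:
        return None
    z, p = circ_rayleigh(phase_set.phases)
    return EntrainmentResult(
        rayleigh_z=float(z),
        rayleigh_p=float(p),
        mrl_boot=float("nan"),
        n_spikes=n,
        significant=bool(p < alpha),
    )


def bootstrap_mrl(
    phase_set: SpikePhaseSet,
    sample_size: int = 50,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    with_replacement: bool = False,
) -> float:
    """Spike-count-controlled MRL: resultant length of ``sample_size`` phases
    per draw, averaged over ``reps`` draws (without replacement by default)."""
    if phase_set.n < sample_size:
        raise ValueError("fewer phases than the bootstrap sample size")
    rng = rng or np.random.default_rng()
    phasors = np.exp(1j * phase_set.phases)
    if with_replacement:
        picks = rng.integers(0, phase_set.n, size=(reps, sample_size))
    else:
        picks = np.argsort(rng.random((reps, phase_set.n)), axis=1)[:, :sample_size]
    r = np.abs(phasors[picks].mean(axis=1))
    return float(min(r.mean(), 1.0))


# ---------------------------------------------------------------------------
# Spike-field coherence


@dataclass
class SfcSpectrum:
    freqs: np.ndarray
    sfc: np.ndarray
    n_spikes: np.ndarray  # eligible spikes per frequency


def _morlet(fs: float, freq: float, cycles: float) -> np.ndarray:
    """L2-normalized complex Morlet wavelet; support ±3.5 Gaussian SDs."""
    sigma_t = cycles / (2 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return w / np.linalg.norm(w)


def spike_field_coherence(
    lfp: ContinuousSignal,
    spikes: SpikeTrain,
    freqs: np.ndarray = SFC_FREQS,
    cycles: float = 6.0,
) -> SfcSpectrum:
    """SFC_f = |mean over spikes of e^{−iθ_k}| from Morlet-wavelet LFP phases.

    Per frequency the LFP is convolved with a six-cycle complex Morlet
    wavelet; θ_k is the analytic phase at spike k's sample.  Spikes within
    half a wavelet length of either record edge are ineligible at that
    frequency (their phase estimate would mix with zero padding).
    """
    freqs = np.asarray(freqs, dtype=float)
    fs = lfp.sampling_rate
    idx = np.array([lfp.time_to_index(t) for t in spikes.timestamps])
    idx = idx[(idx >= 0) & (idx < lfp.n_samples)]
    if idx.size == 0:
        raise ValueError("no spikes inside the LFP record")
    sfc = np.empty(freqs.size)
    n_used = np.empty(freqs.size, dtype=int)
    any_used = False
    for i, f in enumerate(freqs):
        w = _morlet(fs, f, cycles)
        half = w.size // 2
        conv = sps.fftconvolve(lfp.samples, w, mode="same")
        ok = (idx >= half) & (idx < lfp.n_samples - half)
        n_used[i] = int(ok.sum())
        if n_used[i] == 0:
            sfc[i] = np.nan
            continue
        any_used = True
        theta = np.angle(conv[idx[ok]])
        sfc[i] = np.abs(np.mean(np.exp(-1j * theta)))
    if not any_used:
        raise ValueError("all spikes fall inside edge-excluded zones")
    return SfcSpectrum(freqs=freqs, sfc=sfc, n_spikes=n_used)


# ---------------------------------------------------------------------------
# High/low state summary


def state_entrainment_summary(
    units: Mapping[str, Mapping[str, SpikePhaseSet]],
    alpha: float = 0.05,
    min_n: int = 50,
    rng: np.random.Generator | None = None,
):
    """Per-unit high/low entrainment with NormDiff scores and per-state
    proportions of significantly modulated units.

    ``units`` maps unit id → {'high': SpikePhaseSet, 'low': SpikePhaseSet}.
    Units lacking more than ``min_n`` phases in either state are excluded.
    Returns (per-unit DataFrame, {'high': proportion, 'low': proportion}).
    """
    import pandas as pd

    rng = rng or np.random.default_rng()
    rows = []
    for unit_id, states in units.items():
        res = {}
        for state in ("high", "low"):
            r = rayleigh(states[state], min_n=min_n, alpha=alpha)
            if r is None:
                res = None
                break
            r.mrl_boot = bootstrap_mrl(states[state], rng=rng)
            res[state] = r
        if res is None:
            continue
        rows.append(
            {
                "unit_id": unit_id,
                "n_high": res["high"].n_spikes,
                "n_low": res["low"].n_spikes,
                "z_high": res["high"].rayleigh_z,
                "z_low": res["low"].rayleigh_z,
                "p_high": res["high"].rayleigh_p,
                "p_low": res["low"].rayleigh_p,
                "mrl_high": res["high"].mrl_boot,
                "mrl_low": res["low"].mrl_boot,
                "sig_high": res["high"].significant,
                "sig_low": res["low"].significant,
                "normdiff_mrl": norm_diff(res["high"].mrl_boot, res["low"].mrl_boot),
                "normdiff_z": norm_diff(res["high"].rayleigh_z, res["low"].rayleigh_z),
            }
        )
    if not rows:
        raise ValueError("no unit passes the per-state spike-count inclusion")
    table = pd.DataFrame(rows).set_index("unit_id")
    proportions = {
        "high": float(table["sig_high"].mean()),
        "low": float(table["sig_low"].mean()),
    }
    return table, proportions
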