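"""Streaming theta-coherence estimation with artifact gating and thresholding.

This is the core of the closed-loop interface: local field potentials from two
sites are processed in overlapping 1.25 s windows advanced in 250 ms steps.
Each window is cubic-detrended, z-scored against a pre-session baseline, and
the magnitude-squared coherence between the two sites is evaluated on a fixed
1–20 Hz grid (0.5 Hz spacing).  "Theta coherence" is the mean coherence over
6–11 Hz.  Windows are discarded (can never trigger) if more than 1% of either
signal's samples exceed 4 baseline standard deviations, or if mean delta
(1–4 Hz) coherence exceeds mean theta coherence — movement artifacts carry
strong delta power.  Per-subject trigger thresholds sit one standard
deviation above (strong) and below (weak) the subject's mean theta coherence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as sps

from .io import ContinuousSignal

Verdict = Literal["clean", "saturated", "delta_dominant"]


def _default_grid() -> np.ndarray:
    return np.arange(1.0, 20.0 + 1e-9, 0.5)


@dataclass
class WindowSpec:
    """Windowing and spectral-grid configuration for the streaming estimator.

    The protocol-level knobs are the window length, step, frequency grid and the
    theta/delta bands.  ``seg_len``/``seg_overlap`` are the Welch internals:
    0.5 s Hann segments with 50% overlap give K=4 averaged segments per
    1.25 s window while the FFT is zero-padded to resolve the 0.5 Hz grid.
    """

    window_len: float = 1.25
    step: float = 0.25
    freq_grid: np.ndarray = field(default_factory=_default_grid)
    theta_band: tuple[float, float] = (6.0, 11.0)
    delta_band: tuple[float, float] = (1.0, 4.0)
    seg_len: float = 0.5
    seg_overlap: float = 0.5

    def __post_init__(self) -> None:
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if not (0 < self.step <= self.window_len):
            raise ValueError("require 0 < step <= window_len")
        if (np.diff(self.freq_grid) <= 0).any():
            raise ValueError("freq_grid must be strictly increasing")
        for lo, hi in (self.theta_band, self.delta_band):
            if lo < self.freq_grid[0] or hi > self.freq_grid[-1]:
                raise ValueError("bands must lie within the frequency grid")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freq_grid >= lo - 1e-9) & (self.freq_grid <= hi + 1e-9)

    def window_samples(self, fs: float) -> int:
        return int(round(self.window_len * fs))

    def step_samples(self, fs: float) -> int:
        return int(round(self.step * fs))


@dataclass
class BaselineStats:
    """Mean and SD (µV) of a pre-session baseline recording."""

    mean: float
    sd: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("baseline sd must be positive")


def compute_baseline(signal: ContinuousSignal) -> BaselineStats:
    """Baseline statistics from a calibration recording (nominally ~10 min)."""
    return BaselineStats(
        mean=float(np.mean(signal.samples)),
        sd=float(np.std(signal.samples)),
        duration=signal.duration,
    )


@dataclass
class CoherenceEpoch:
    """One analysis window: coherence spectrum, theta/delta summaries, verdict."""

    t_start: float
    coherence: np.ndarray
    theta_value: float
    delta_value: float
    verdict: Verdict

    @property
    def clean(self) -> bool:
        return self.verdict == "clean"


@dataclass
class ThresholdProfile:
    """Per-subject trigger thresholds: mean ± 1 SD of clean theta coherence."""

    mean: float
    sd: float
    subject_id: str = ""
    n_samples: int = 0

    @property
    def high(self) -> float:
        return self.mean + self.sd

    @property
    def low(self) -> float:
        return self.mean - self.sd

    def to_text(self) -> str:
        return (
            f"subject_id\t{self.subject_id}\nmean\t{self.mean!r}\nsd\t{self.sd!r}\n"
            f"high\t{self.high!r}\nlow\t{self.low!r}\nn_samples\t{self.n_samples}\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "ThresholdProfile":
        fields = dict(line.split("\t") for line in text.strip().splitlines())
        return cls(
            mean=float(fields["mean"]),
            sd=float(fields["sd"]),
            subject_id=fields.get("subject_id", ""),
            n_samples=int(fields.get("n_samples", 0)),
        )


# ---------------------------------------------------------------------------
# Window-level primitives


def detrend_poly3(window_samples: np.ndarray) -> np.ndarray:
    """Subtract the least-squares cubic fit from one analysis window."""
    x = np.asarray(window_samples, dtype=float)
    if x.size < 8:
        raise ValueError("window shorter than 8 samples")
    # normalized abscissa for conditioning; the fitted subspace is identical
    u = np.linspace(-1.0, 1.0, x.size)
    coeffs = npoly.polyfit(u, x, deg=3)
    return x - npoly.polyval(u, coeffs)


def zscore_with_baseline(window_samples: np.ndarray, baseline: BaselineStats) -> np.ndarray:
    """Z-score a window against pre-session baseline statistics."""
    if baseline.sd <= 0:
        raise ValueError("baseline sd must be positive")
    return (np.asarray(window_samples, dtype=float) - baseline.mean) / baseline.sd


def msc_welch(
    x_window: np.ndarray,
    y_window: np.ndarray,
    spec: WindowSpec,
    sampling_rate: float,
) -> np.ndarray:
    """Magnitude-squared coherence |Pxy|²/(Pxx·Pyy) on ``spec.freq_grid``.

    Segment-averaged (Welch) cross/auto spectra with Hann-tapered segments of
    ``spec.seg_len`` seconds and ``spec.seg_overlap`` fractional overlap; the
    FFT length is zero-padded so that every grid frequency falls on a bin.
    """
    x = np.asarray(x_window, dtype=float)
    y = np.asarray(y_window, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch between the two windows")
    nperseg = int(round(spec.seg_len * sampling_rate))
    if x.size < 2 * nperseg:
        raise ValueError("window must cover at least two Welch segments")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: coherence undefined")
    noverlap = int(round(nperseg * spec.seg_overlap))
    grid_step = float(np.min(np.diff(spec.freq_grid)))
    nfft = max(nperseg, int(round(sampling_rate / grid_step)))
    f, coh = sps.coherence(
        x,
        y,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend=False,
    )
    idx = np.searchsorted(f, spec.freq_grid)
    idx = np.clip(idx, 0, f.size - 1)
    # snap to nearest bin (grid frequencies are constructed to be exact bins)
    left = np.clip(idx - 1, 0, f.size - 1)
    use_left = np.abs(f[left] - spec.freq_grid) < np.abs(f[idx] - spec.freq_grid)
    idx = np.where(use_left, left, idx)
    if np.max(np.abs(f[idx] - spec.freq_grid)) > grid_step / 2:
        raise ValueError("frequency grid cannot be resolved at this sampling rate")
    return np.clip(coh[idx], 0.0, 1.0)


def welch_segment_count(spec: WindowSpec, sampling_rate: float) -> int:
    """Number of Welch segments averaged per analysis window."""
    nperseg = int(round(spec.seg_len * sampling_rate))
    noverlap = int(round(nperseg * spec.seg_overlap))
    n = spec.window_samples(sampling_rate)
    return 1 + (n - nperseg) // (nperseg - noverlap)


def theta_summary(coherence: np.ndarray, spec: WindowSpec) -> tuple[float, float]:
    """Mean coherence over the theta and delta bands (inclusive endpoints)."""
    coherence = np.asarray(coherence, dtype=float)
    out = []
    for band in (spec.theta_band, spec.delta_band):
        mask = spec.band_mask(band)
        if not mask.any():
            raise ValueError(f"band {band} contains no grid points")
        out.append(float(coherence[mask].mean()))
    return out[0], out[1]


def artifact_verdict(
    x_z: np.ndarray,
    y_z: np.ndarray,
    theta_value: float,
    delta_value: float,
    saturation_sd: float = 4.0,
    max_fraction: float = 0.01,
) -> Verdict:
    """Artifact gate for one window pair of z-scored samples.

    Saturation is checked first: if the fraction of samples with |z| beyond
    ``saturation_sd`` strictly exceeds ``max_fraction`` in either signal, the
    window's spectra are meaningless and the delta/theta comparison is never
    consulted.  Otherwise the window is delta-dominant when mean delta
    coherence exceeds mean theta coherence.  Exactly ``max_fraction``
    saturated samples passes (strict inequality).
    """
    x_z = np.asarray(x_z, dtype=float)
    y_z = np.asarray(y_z, dtype=float)
    if x_z.shape != y_z.shape:
        raise ValueError("length mismatch between the two windows")
    for z in (x_z, y_z):
        if np.mean(np.abs(z) > saturation_sd) > max_fraction:
            return "saturated"
    if delta_value > theta_value:
        return "delta_dominant"
    return "clean"


# ---------------------------------------------------------------------------
# Streaming pipeline


def iter_epochs(
    x: ContinuousSignal,
    y: ContinuousSignal,
    baseline_x: BaselineStats,
    baseline_y: BaselineStats,
    spec: WindowSpec | None = None,
    saturation_sd: float = 4.0,
    max_fraction: float = 0.01,
    t_stop: float | None = None,
) -> Iterator[CoherenceEpoch]:
    """Slide the analysis window over a time-aligned signal pair.

    Windows are only evaluated once a full window of data exists; zero-variance
    windows (e.g. hard-clipped flat) are emitted as ``saturated`` with a NaN
    spectrum since no coherence is defined for them.
    """
    spec = spec or WindowSpec()
    if x.sampling_rate != y.sampling_rate:
        raise ValueError("sampling_rate mismatch between streams")
    fs = x.sampling_rate
    n_win = spec.window_samples(fs)
    n_step = spec.step_samples(fs)
    n = min(x.n_samples, y.n_samples)
    if n < n_win:
        raise ValueError("stream shorter than one window")
    for start in range(0, n - n_win + 1, n_step):
        t_start = x.start_time + start / fs
        if t_stop is not None and t_start + spec.window_len > t_stop + 1e-12:
            break
        xw = detrend_poly3(x.samples[start : start + n_win])
        yw = detrend_poly3(y.samples[start : start + n_win])
        xz = zscore_with_baseline(xw + baseline_x.mean, baseline_x)
        yz = zscore_with_baseline(yw + baseline_y.mean, baseline_y)
        try:
            coh = msc_welch(xz, yz, spec, fs)
        except ValueError:
            yield CoherenceEpoch(
                t_start=t_start,
                coherence=np.full(spec.freq_grid.shape, np.nan),
                theta_value=float("nan"),
                delta_value=float("nan"),
                verdict="saturated",
            )
            continue
        theta, delta = theta_summary(coh, spec)
        verdict = artifact_verdict(xz, yz, theta, delta, saturation_sd, max_fraction)
        yield CoherenceEpoch(
            t_start=t_start,
            coherence=coh,
            theta_value=theta,
            delta_value=delta,
            verdict=verdict,
        )


@dataclass
class DetectionOutcome:
    """Result of one detector run: trigger (or timeout) time and its cause."""

    trigger_time: float
    cause: Literal["threshold", "timeout"]
    n_epochs: int = 0
    n_clean: int = 0


def stream_detect(
    x: ContinuousSignal,
    y: ContinuousSignal,
    baseline_x: BaselineStats,
    baseline_y: BaselineStats,
    spec: WindowSpec,
    thresholds: ThresholdProfile,
    mode: Literal["high", "low"],
    timeout: float = 30.0,
) -> DetectionOutcome:
    """Run the closed-loop detector on a time-aligned stream pair.

    In ``high`` mode the first clean window whose theta coherence reaches the
    subject's high threshold triggers; in ``low`` mode, the low threshold
    (from below).  Non-clean windows can never trigger.  If no clean window
    crosses within ``timeout`` seconds of stream onset the outcome is a
    timeout.  Trigger time is the end time of the triggering window.
    """
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    n_epochs = n_clean = 0
    t0 = x.start_time
    for epoch in iter_epochs(x, y, baseline_x, baseline_y, spec):
        t_end = epoch.t_start + spec.window_len
        if t_end - t0 > timeout + 1e-12:
            break
        n_epochs += 1
        if not epoch.clean:
            continue
        n_clean += 1
        crossed = (
            epoch.theta_value >= thresholds.high
            if mode == "high"
            else epoch.theta_value <= thresholds.low
        )
        if crossed:
            return DetectionOutcome(
                trigger_time=t_end - t0,
                cause="threshold",
                n_epochs=n_epochs,
                n_clean=n_clean,
            )
    return DetectionOutcome(
        trigger_time=timeout, cause="timeout", n_epochs=n_epochs, n_clean=n_clean
    )


def calibrate_thresholds(
    theta_values: Sequence[float], subject_id: str = ""
) -> ThresholdProfile:
    """Per-subject thresholds from a distribution of clean theta-coherence values.

    High/low triggers are the mean ± one sample standard deviation (n−1
    denominator) of the supplied values; each subject therefore carries a
    unique numerical threshold pair.
    """
    vals = np.asarray(theta_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 theta values to calibrate")
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("theta coherence values must lie in [0, 1]")
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        raise ValueError("degenerate distribution: all theta values equal")
    return ThresholdProfile(
        mean=float(np.mean(vals)), sd=sd, subject_id=subject_id, n_samples=vals.size
    )
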