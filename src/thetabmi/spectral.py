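"""Offline spectral analyses: multitaper power, theta peak frequency,
event-locked coherograms, normalized difference scores, and the
coherence-autocorrelation-versus-shuffle analysis.

Power spectra use Slepian (DPSS) tapers — three tapers with a
time-bandwidth product of 2 — averaged and log10-transformed to flatten the
1/f power law.  The offline theta band for power comparisons is 6–9 Hz; the
real-time detection band stays 6–11 Hz (both are module constants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.signal.windows import dpss

from .coherence import BaselineStats, WindowSpec, iter_epochs, msc_welch, theta_summary
from .io import ContinuousSignal, EventLog, extract_epochs

#: Offline theta band (Hz) used for power comparisons.
THETA_BAND_OFFLINE = (6.0, 9.0)
#: Real-time theta band (Hz) used by the closed-loop detector.
THETA_BAND_RT = (6.0, 11.0)


@dataclass
class SpectralResult:
    """Multitaper log10 power spectrum."""

    freqs: np.ndarray
    power: np.ndarray  # log10 power
    n_tapers: int = 3
    time_bandwidth: float = 2.0


def psd_multitaper(
    epoch: np.ndarray,
    sampling_rate: float,
    n_tapers: int = 3,
    time_bandwidth: float = 2.0,
) -> SpectralResult:
    """Slepian-taper averaged power spectrum of one epoch, log10-transformed.

    Frequency resolution is set by the epoch length; the half-bandwidth is
    ``time_bandwidth / duration`` Hz.
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("epoch must be a 1-D array of at least 8 samples")
    if np.ptp(x) == 0:
        raise ValueError("all-zero (constant) epoch: power undefined")
    n = x.size
    tapers = dpss(n, NW=time_bandwidth, Kmax=n_tapers)
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2
    power = spectra.mean(axis=0) / sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return SpectralResult(
        freqs=freqs,
        power=np.log10(np.maximum(power, np.finfo(float).tiny)),
        n_tapers=n_tapers,
        time_bandwidth=time_bandwidth,
    )


def theta_peak_frequency(
    result: SpectralResult, band: tuple[float, float] = (4.0, 12.0)
) -> float:
    """Frequency of maximum power within ``band``; ties break toward the
    lower frequency (argmax returns the first maximum)."""
    lo, hi = band
    mask = (result.freqs >= lo) & (result.freqs <= hi)
    if not mask.any():
        raise ValueError("band does not intersect the frequency axis")
    sub_f = result.freqs[mask]
    sub_p = result.power[mask]
    return float(sub_f[np.argmax(sub_p)])


@dataclass
class Coherogram:
    """Event-locked time-frequency coherence, averaged across events."""

    times: np.ndarray  # seconds relative to the event (window end times)
    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n_times), in [0, 1]
    n_events: int = 0


def event_coherogram(
    x: ContinuousSignal,
    y: ContinuousSignal,
    events: EventLog,
    kind: str = "choice_entry",
    window: tuple[float, float] = (2.0, 0.5),
    moving: WindowSpec | None = None,
) -> Coherogram:
    """Moving-window coherence inside event-locked epochs, averaged over events.

    Epochs span ``window = (pre, post)`` seconds around each event; inside
    each epoch the coherence window slides by ``moving.step``.  The time axis
    is the window-end time relative to the event.
    """
    moving = moving or WindowSpec()
    fs = x.sampling_rate
    if y.sampling_rate != fs:
        raise ValueError("sampling_rate mismatch")
    rep_x = extract_epochs(x, events, kind, window)
    rep_y = extract_epochs(y, events, kind, window)
    if not rep_x.epochs:
        raise ValueError("no complete event epochs")
    n_win = moving.window_samples(fs)
    n_step = moving.step_samples(fs)
    n_len = len(rep_x.epochs[0])
    if n_len < n_win:
        raise ValueError("epoch shorter than one moving window")
    starts = np.arange(0, n_len - n_win + 1, n_step)
    times = -window[0] + (starts + n_win) / fs
    acc = np.zeros((moving.freq_grid.size, starts.size))
    for ex, ey in zip(rep_x.epochs, rep_y.epochs):
        for j, s in enumerate(starts):
            acc[:, j] += msc_welch(ex[s : s + n_win], ey[s : s + n_win], moving, fs)
    values = acc / len(rep_x.epochs)
    return Coherogram(times=times, freqs=moving.freq_grid.copy(), values=values,
                      n_events=len(rep_x.epochs))


def norm_diff(x, y):
    """Normalized difference score (X − Y)/(X + Y), elementwise on arrays.

    Bounded in [−1, 1] for nonnegative inputs and antisymmetric in its
    arguments; undefined (raises) where X + Y = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = x + y
    if np.any(denom == 0):
        raise ValueError("norm_diff undefined where X + Y = 0")
    out = (x - y) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class CoherenceSeries:
    """Theta-coherence values on a uniform step grid (the moving-window series)."""

    t: np.ndarray
    theta_values: np.ndarray
    step: float = 0.25


def coherence_series(
    x: ContinuousSignal,
    y: ContinuousSignal,
    baseline_x: BaselineStats,
    baseline_y: BaselineStats,
    spec: WindowSpec | None = None,
    clean_only: bool = False,
) -> CoherenceSeries:
    """Moving-window theta-coherence series over a signal pair."""
    spec = spec or WindowSpec()
    t, v = [], []
    for ep in iter_epochs(x, y, baseline_x, baseline_y, spec):
        if clean_only and not ep.clean:
            continue
        t.append(ep.t_start)
        v.append(ep.theta_value)
    return CoherenceSeries(np.asarray(t), np.asarray(v), step=spec.step)


@dataclass
class AutocorrResult:
    lags: np.ndarray
    autocorr: np.ndarray
    null_low: np.ndarray  # 2.5th percentile of the shuffle null per lag
    null_high: np.ndarray  # 97.5th percentile
    sim_low: np.ndarray  # simultaneous 95% band over the reported lags
    sim_high: np.ndarray
    min_lag: int = 5

    @property
    def reported(self) -> np.ndarray:
        """Mask of lags at which real-vs-null comparison is meaningful."""
        return self.lags >= self.min_lag - 1

    def inside_simultaneous_band(self) -> bool:
        m = self.reported
        return bool(
            np.all((self.autocorr[m] >= self.sim_low[m]) & (self.autocorr[m] <= self.sim_high[m]))
        )


def _autocorr(v: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased autocorrelation normalized by lag 0 (guarantees |r| ≤ 1)."""
    v = v - v.mean()
    denom = float(np.dot(v, v))
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    return np.array([np.dot(v[: v.size - k], v[k:]) / denom for k in range(max_lag + 1)])


def coherence_autocorr(
    series: CoherenceSeries,
    n_shuffles: int = 500,
    min_lag: int = 5,
    max_lag: int | None = None,
    rng: np.random.Generator | None = None,
) -> AutocorrResult:
    """Autocorrelation of the theta series against a temporally shuffled null.

    The null is built from random temporal permutations of the same values
    (the multiset is preserved exactly).  Because consecutive windows share
    samples (window length exceeds the step), real-vs-null comparisons are
    only meaningful from ``min_lag`` onward (lag index ≥ min_lag − 1 relative
    to 0); shorter lags are autocorrelated by construction.

    Two null bands are returned: a pointwise central-95% band per lag, and a
    simultaneous band (calibrated on the max studentized deviation across
    the reported lags) whose joint coverage over all reported lags is 95% —
    the appropriate reference when asking whether a whole curve stays
    inside the null.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    v = np.asarray(series.theta_values, dtype=float)
    if v.size <= min_lag + 1:
        raise ValueError("series too short for the requested minimum lag")
    rng = rng or np.random.default_rng()
    if max_lag is None:
        max_lag = min(v.size // 2, 40)
    real = _autocorr(v, max_lag)
    null = np.empty((n_shuffles, max_lag + 1))
    for i in range(n_shuffles):
        null[i] = _autocorr(rng.permutation(v), max_lag)
    lags = np.arange(max_lag + 1)
    mu = null.mean(axis=0)
    sd = np.maximum(null.std(axis=0), 1e-12)
    reported = lags >= min_lag - 1
    max_dev = np.max(np.abs(null[:, reported] - mu[reported]) / sd[reported], axis=1)
    q = float(np.percentile(max_dev, 95))
    return AutocorrResult(
        lags=lags,
        autocorr=real,
        null_low=np.percentile(null, 2.5, axis=0),
        null_high=np.percentile(null, 97.5, axis=0),
        sim_low=mu - q * sd,
        sim_high=mu + q * sd,
        min_lag=min_lag,
    )
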