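"""Behavioral quantification: IdPhi head-movement complexity, distance
traveled, and time-to-choice.

IdPhi is the time integral of absolute angular velocity of the head-position
trajectory: positions are Gaussian-smoothed, x/y velocities estimated by a
discrete time-adaptive windowing scheme (the window around each sample grows
as long as the trajectory segment stays within a chord-fit tolerance, so
stationary jitter is not differentiated into noise), the heading Phi is the
four-quadrant angle of (dX, dY), and dPhi comes from the same adaptive
windowing applied to the unwrapped heading.  One IdPhi score summarizes one
trial; it is zero for straight runs and grows with head sweeps.

Scores are unit-bearing only if the track carries a cm scale; otherwise they
are in native tracker units (the angular quantities are unit-free either way).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BehaviorTrack, EventLog


def smooth_track(track: BehaviorTrack, kernel_width: float = 0.2) -> BehaviorTrack:
    """Gaussian-weighted moving average of x and y (σ = width/5, kernel
    truncated at the window and renormalized, so endpoints stay unbiased
    for constant signals)."""
    if kernel_width <= 0:
        raise ValueError("kernel_width must be positive")
    duration = track.t[-1] - track.t[0] if track.n_points > 1 else 0.0
    if kernel_width > duration:
        raise ValueError("kernel wider than track duration")
    dt = float(np.median(np.diff(track.t)))
    half = max(1, int(round(kernel_width / (2 * dt))))
    sigma = max(kernel_width / 5.0 / dt, 1e-9)
    k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    norm = np.convolve(np.ones(track.n_points), k, mode="same")
    xs = np.convolve(track.x, k, mode="same") / norm
    ys = np.convolve(track.y, k, mode="same") / norm
    return BehaviorTrack(xs, ys, track.t.copy(), scale_cm_per_unit=track.scale_cm_per_unit)


@dataclass
class VelocityEstimate:
    dx: np.ndarray
    dy: np.ndarray
    window_sizes: np.ndarray  # half-widths used per point (samples)


def _adaptive_derivative(
    values: np.ndarray,
    t: np.ndarray,
    tolerance: float,
    min_window: int,
    max_window: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point derivative of ``values`` (n × d) by adaptive windowing.

    At each sample the symmetric window grows (up to ``max_window`` total
    samples) while every interior point stays within ``tolerance`` of the
    straight segment joining the window endpoints; the derivative is then
    the endpoint difference quotient over the largest accepted window.
    """
    if max_window < min_window or min_window < 2:
        raise ValueError("require max_window >= min_window >= 2")
    v = np.atleast_2d(np.asarray(values, dtype=float).T).T  # (n, d)
    n = v.shape[0]
    if n < min_window:
        raise ValueError("track shorter than min_window")
    h_min = max(1, (min_window - 1) // 2)
    h_max = max(h_min, (max_window - 1) // 2)
    deriv = np.zeros_like(v)
    used = np.zeros(n, dtype=int)
    for i in range(n):
        h_cap = min(h_max, i, n - 1 - i)
        if h_cap == 0:  # record edge: one-sided neighbor difference
            a, b = max(0, i - 1), min(n - 1, i + 1)
            deriv[i] = (v[b] - v[a]) / (t[b] - t[a])
            used[i] = 0
            continue
        h_lo = min(h_min, h_cap)
        h_best = h_lo
        for h in range(h_lo, h_cap + 1):
            a, b = i - h, i + h
            frac = (t[a + 1 : b] - t[a]) / (t[b] - t[a])
            chord = v[a] + np.outer(frac, v[b] - v[a])
            err = np.max(np.linalg.norm(v[a + 1 : b] - chord, axis=1)) if b > a + 1 else 0.0
            if err > tolerance:
                break
            h_best = h
        a, b = i - h_best, i + h_best
        deriv[i] = (v[b] - v[a]) / (t[b] - t[a])
        used[i] = h_best
    return deriv, used


def adaptive_velocity(
    track: BehaviorTrack,
    tolerance: float = 1.0,
    min_window: int = 3,
    max_window: int = 15,
) -> VelocityEstimate:
    """x/y velocities by discrete time-adaptive windowing (chord-fit rule)."""
    pos = np.column_stack([track.x, track.y])
    deriv, used = _adaptive_derivative(pos, track.t, tolerance, min_window, max_window)
    return VelocityEstimate(dx=deriv[:, 0], dy=deriv[:, 1], window_sizes=used)


@dataclass
class IdPhiResult:
    phi: np.ndarray
    dphi: np.ndarray
    idphi: float


def idphi(
    track: BehaviorTrack,
    tolerance: float = 1.0,
    min_window: int = 3,
    max_window: int = 15,
    phi_tolerance: float = 0.05,
) -> IdPhiResult:
    """Integrated absolute angular velocity of the trajectory heading.

    Heading Phi is the four-quadrant angle of the velocity vector; dPhi is
    obtained by the same adaptive windowing applied to the unwrapped Phi
    (``phi_tolerance`` radians); IdPhi is the time integral of |dPhi|.
    """
    vel = adaptive_velocity(track, tolerance, min_window, max_window)
    speed = np.hypot(vel.dx, vel.dy)
    if np.all(speed == 0):
        warnings.warn("all-zero velocity: heading undefined, IdPhi set to 0")
        z = np.zeros(track.n_points)
        return IdPhiResult(phi=z, dphi=z.copy(), idphi=0.0)
    phi = np.unwrap(np.arctan2(vel.dy, vel.dx))
    dphi, _ = _adaptive_derivative(phi[:, None], track.t, phi_tolerance, min_window, max_window)
    dphi = dphi[:, 0]
    return IdPhiResult(phi=phi, dphi=dphi, idphi=float(np.trapezoid(np.abs(dphi), track.t)))


def distance_traveled(
    track: BehaviorTrack, window: tuple[float, float] | None = None
) -> float:
    """Sum of successive Euclidean steps, optionally restricted to a
    [t0, t1] time window (e.g. the last 1.25 s before the trigger)."""
    x, y, t = track.x, track.y, track.t
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        x, y = x[sel], y[sel]
    if x.size < 2:
        raise ValueError("need at least 2 points in the window")
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def normalize_session(distances) -> np.ndarray:
    """Session-wise min-max normalization of per-trial distances to [0, 1];
    a degenerate session (max = min) maps to all zeros with a warning."""
    d = np.asarray(distances, dtype=float)
    lo, hi = d.min(), d.max()
    if hi == lo:
        warnings.warn("degenerate session: all distances equal; normalized to 0")
        return np.zeros_like(d)
    return (d - lo) / (hi - lo)


def time_to_choice(events: EventLog) -> pd.DataFrame:
    """Per-trial latency from central door opening to choice-point exit.

    Each ``door_open`` is matched with the first ``choice_exit`` that
    follows it (before the next ``door_open``).  Unmatched doors are
    flagged ``missing``; an exit preceding its door is an ordering
    violation and is flagged rather than returned as a negative latency.
    """
    doors = events.times_of("door_open")
    exits = list(events.times_of("choice_exit"))
    rows = []
    j = 0  # pointer into unconsumed exits
    for i, td in enumerate(doors):
        t_next = doors[i + 1] if i + 1 < doors.size else np.inf
        flag, t_choice = "", np.nan
        if j < len(exits) and exits[j] <= td:
            flag = "ordering_violation"  # an unmatched exit precedes this door
            j += 1
        elif j < len(exits) and exits[j] < t_next:
            t_choice = exits[j]
            j += 1
        else:
            flag = "missing"
        rows.append({"trial": i, "t_door": td, "t_choice": t_choice,
                     "latency": t_choice - td if flag == "" else np.nan,
                     "flag": flag})
    return pd.DataFrame(rows)
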