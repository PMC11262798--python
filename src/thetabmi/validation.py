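"""End-to-end validation studies on synthetic data.

Each function runs one self-contained study — scheduler bookkeeping, the
streaming coherence estimator against closed-form references, artifact
gating against ground truth, Granger direction recovery, circular-statistics
recovery, behavioral geometry, the autocorrelation shuffle null, and the
p-value machinery — and returns the measured quantities in a plain dict.
The reproduction script and the test suite both drive these functions; all
randomness flows from the supplied generator.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from scipy import stats as sstats
from scipy.signal.windows import hann

from . import scheduler as sched
from . import stats as tstats
from .behavior import distance_traveled, idphi
from .coherence import (
    WindowSpec,
    calibrate_thresholds,
    compute_baseline,
    iter_epochs,
    msc_welch,
    welch_segment_count,
)
from .granger import best_order_bic, bivariate_gc, multivariate_gc
from .io import BehaviorTrack, ContinuousSignal, SpikeTrain
from .spectral import CoherenceSeries, coherence_autocorr
from .spike_lfp import SpikePhaseSet, bootstrap_mrl, rayleigh, spike_field_coherence
from .synth import (
    CLEAN_THETA_SPEC,
    CoherenceStateTrack,
    OscillatorSpec,
    gen_coupled_lfp,
    gen_trajectory,
    inject_artifacts,
)


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def welch_coherence_bias_oracle(nperseg: int, step: int, n_segments: int) -> float:
    """Closed-form expected MSC of independent noise under Welch averaging:
    1/K_eff with K_eff from the taper overlap correlations."""
    w = hann(nperseg)
    denom = float(np.sum(w * w))
    rho = np.array(
        [
            np.sum(w[: nperseg - m * step] * w[m * step :]) / denom
            if m * step < nperseg
            else 0.0
            for m in range(1, n_segments)
        ]
    )
    k_eff = n_segments**2 / (
        n_segments + 2 * np.sum((n_segments - np.arange(1, n_segments)) * rho**2)
    )
    return float(1.0 / k_eff)


# ---------------------------------------------------------------------------


def scheduler_composition(rng: np.random.Generator, n_blocks: int = 100) -> dict:
    """Block composition of seeded DA and CD sessions with no timeouts."""
    def detector(mode, timeout):
        return (8.0, "threshold")

    da = sched.records_to_frame(
        sched.run_session(sched.ProtocolSpec.delayed_alternation(), n_blocks, detector, rng)
    )
    per_block = da.groupby("block")["type"].value_counts().unstack(fill_value=0)
    cd = sched.records_to_frame(
        sched.run_session(sched.ProtocolSpec.conditional_discrimination(), n_blocks, detector, rng)
    )
    return {
        "da_random_per_block": float(per_block["random"].mean()),
        "da_experimental_per_block": float((per_block["high"] + per_block["low"]).mean()),
        "da_yoked_per_block": float((per_block["yoked_high"] + per_block["yoked_low"]).mean()),
        "da_composition_exact": bool(
            (per_block[["high", "low", "yoked_high", "yoked_low"]] == 1).all().all()
            and (per_block["random"] == 6).all()
        ),
        "cd_yoked_trial_pct": float(100.0 * (cd["type"] == "yoked_high").mean()),
    }


def yoking_exactness(rng: np.random.Generator, n_trials: int = 1000) -> dict:
    """Delay replay exactness and the timeout substitution rule."""
    proto = sched.ProtocolSpec.delayed_alternation()

    def detector(mode, timeout):
        d = float(rng.uniform(2.0, timeout + 10.0))
        return (d, "threshold") if d < timeout else (timeout, "timeout")

    records = sched.run_session(proto, n_trials // proto.block_size, detector, rng)
    by_index = {r.index: r for r in records}
    diffs = [
        abs(r.delay - by_index[r.paired_with].delay)
        for r in records
        if r.type.startswith("yoked")
    ]
    n_timeouts = sum(r.trigger_cause == "timeout" for r in records)
    n_yoked = sum(r.type.startswith("yoked") for r in records)
    n_converted = sum(r.was_yoked for r in records)
    return {
        "n_trials": len(records),
        "yoked_delay_max_abs_diff": float(max(diffs)) if diffs else 0.0,
        "yoked_slots_converted_per_timeout": float(n_converted / n_timeouts)
        if n_timeouts
        else 0.0,
        "yoked_plus_converted_equals_quota": bool(
            n_yoked + n_converted == 2 * (len(records) // proto.block_size)
        ),
    }


def coherence_estimator(
    rng: np.random.Generator,
    n_bias_windows: int = 1000,
    n_state_windows: int = 500,
    sampling_rate: float = 1000.0,
) -> dict:
    """Identical-signal identity, Welch bias against the closed form, and
    high/low state separability."""
    spec = WindowSpec()
    n_win = spec.window_samples(sampling_rate)
    x = rng.standard_normal(n_win)
    identical = msc_welch(x, x, spec, sampling_rate)
    bias_measured = float(
        np.mean(
            [
                msc_welch(
                    rng.standard_normal(n_win), rng.standard_normal(n_win), spec, sampling_rate
                ).mean()
                for _ in range(n_bias_windows)
            ]
        )
    )
    nperseg = int(round(spec.seg_len * sampling_rate))
    oracle = welch_coherence_bias_oracle(
        nperseg, nperseg // 2, welch_segment_count(spec, sampling_rate)
    )

    osc = OscillatorSpec(sampling_rate=sampling_rate)
    hi, lo = [], []
    while len(hi) < n_state_windows or len(lo) < n_state_windows:
        states = CoherenceStateTrack.alternating(40, 3.0, 3.0)
        a, b = gen_coupled_lfp(osc, osc, states, seed=_seed(rng))
        mask = states.state_mask(a.n_samples, sampling_rate)
        ba, bb = compute_baseline(a), compute_baseline(b)
        for e in iter_epochs(a, b, ba, bb, spec):
            i0 = int(e.t_start * sampling_rate)
            frac = mask[i0 : i0 + n_win].mean()
            if frac == 1.0:
                hi.append(e.theta_value)
            elif frac == 0.0:
                lo.append(e.theta_value)
    hi, lo = hi[:n_state_windows], lo[:n_state_windows]
    _, p = sstats.mannwhitneyu(hi, lo, alternative="greater")
    return {
        "identical_signal_min_coherence": float(identical.min()),
        "independent_noise_mean_coherence": bias_measured,
        "welch_bias_oracle": oracle,
        "welch_bias_rel_error_pct": float(100.0 * abs(bias_measured - oracle) / oracle),
        "high_minus_low_theta_coherence": float(np.mean(hi) - np.mean(lo)),
        "state_separation_log10_p": float(np.log10(max(p, 1e-300))),
    }


def threshold_calibration(rng: np.random.Generator, n_values: int = 10000) -> dict:
    vals = np.clip(rng.normal(0.5, 0.1, n_values), 0.0, 1.0)
    prof = calibrate_thresholds(vals)
    span_err = abs((prof.high - prof.low) - 2 * prof.sd)
    return {
        "calibration_mean_abs_error": float(abs(prof.mean - 0.5)),
        "calibration_sd_abs_error": float(abs(prof.sd - 0.1)),
        "threshold_span_err_ulps": float(span_err / np.spacing(2 * prof.sd)),
    }


def artifact_gating(
    rng: np.random.Generator,
    n_sat_windows: int = 300,
    n_clean_windows: int = 1000,
    sampling_rate: float = 1000.0,
) -> dict:
    """Detection of injected saturation and coherent delta bursts; false
    rejections on uncorrupted windows in the clean theta-dominant regime."""
    spec = WindowSpec()
    n_win = spec.window_samples(sampling_rate)
    osc = OscillatorSpec(sampling_rate=sampling_rate, **CLEAN_THETA_SPEC)

    # --- saturation: corrupt isolated windows at 2% and check the verdict
    states = CoherenceStateTrack(("high",), (float(n_sat_windows * 1.25),))
    x, y = gen_coupled_lfp(osc, osc, states, seed=_seed(rng), high_mix=1.0)
    bx, by = compute_baseline(x), compute_baseline(y)
    sat_detected = 0
    for i in range(n_sat_windows):
        seg = ContinuousSignal(x.samples[i * n_win : (i + 1) * n_win].copy(), sampling_rate)
        seg_c, _ = inject_artifacts(seg, 0.02, 8.0 * bx.sd, 0.0, seed=_seed(rng))
        other = ContinuousSignal(y.samples[i * n_win : (i + 1) * n_win], sampling_rate)
        e = next(iter_epochs(seg_c, other, bx, by, spec))
        sat_detected += e.verdict == "saturated"

    # --- coherent delta bursts at 3x the theta amplitude, in the default
    # (moderately coupled) regime the interface normally sees
    osc_default = OscillatorSpec(sampling_rate=sampling_rate)
    states = CoherenceStateTrack(("high",), (400.0,))
    a, b = gen_coupled_lfp(osc_default, osc_default, states, seed=_seed(rng))
    theta_amp = float(np.std(a.samples))
    burst_seed = _seed(rng)
    ac, truth = inject_artifacts(a, 0.0, 2000.0, 4.0, seed=burst_seed, burst_amp=3 * theta_amp)
    bc, _ = inject_artifacts(b, 0.0, 2000.0, 4.0, seed=burst_seed, burst_amp=3 * theta_amp)
    ba, bb = compute_baseline(a), compute_baseline(b)
    covered = rejected = 0
    for e in iter_epochs(ac, bc, ba, bb, spec):
        if truth.covering(e.t_start, e.t_start + spec.window_len, "delta_burst"):
            covered += 1
            rejected += e.verdict != "clean"

    # --- clean windows: no artifact, no rejection expected
    n_states = int(np.ceil(n_clean_windows * 0.25 * 1.1 + 2))
    states = CoherenceStateTrack(("high",), (float(n_states),))
    cx, cy = gen_coupled_lfp(osc, osc, states, seed=_seed(rng), high_mix=1.0)
    bcx, bcy = compute_baseline(cx), compute_baseline(cy)
    verdicts = [e.verdict for e in iter_epochs(cx, cy, bcx, bcy, spec)][:n_clean_windows]
    return {
        "saturation_detection_pct": float(100.0 * sat_detected / n_sat_windows),
        "delta_burst_detection_pct": float(100.0 * rejected / covered) if covered else float("nan"),
        "n_burst_windows": covered,
        "clean_false_rejection_pct": float(
            100.0 * np.mean([v != "clean" for v in verdicts])
        ),
        "n_clean_windows": len(verdicts),
    }


def granger_validation(
    rng: np.random.Generator,
    n_seeds: int = 100,
    length: int = 20000,
    n_bic_runs: int = 100,
) -> dict:
    """Direction recovery, integral identity, BIC order recovery, and
    conditional suppression of an indirect chain link."""
    fs = 200.0
    correct_dir = 0
    reverse_vals, ident_errs = [], []
    for _ in range(n_seeds):
        x = rng.standard_normal(length)
        y = np.empty(length)
        y[0] = rng.standard_normal()
        y[1:] = 0.8 * x[:-1] + rng.standard_normal(length - 1)
        res = bivariate_gc(x, y, k=2, sampling_rate=fs)
        correct_dir += res.time_domain_gc["x->y"] > res.time_domain_gc["y->x"]
        reverse_vals.append(res.time_domain_gc["y->x"])
        ident_errs.append(
            abs(res.spectral_mean("x->y") - res.time_domain_gc["x->y"])
            / res.time_domain_gc["x->y"]
        )

    bic_hits = 0
    for _ in range(n_bic_runs):
        e = rng.standard_normal(5000)
        x = np.zeros(5000)
        for t in range(2, 5000):
            x[t] = 0.5 * x[t - 1] - 0.4 * x[t - 2] + e[t]
        bic_hits += best_order_bic(x, max_order=20) == 2

    T = length
    x = rng.standard_normal(T)
    y = np.zeros(T)
    z = np.zeros(T)
    for t in range(1, T):
        y[t] = 0.5 * y[t - 1] + 0.8 * x[t - 1] + rng.standard_normal()
        z[t] = 0.5 * z[t - 1] + 0.8 * y[t - 1] + rng.standard_normal()
    cond = multivariate_gc([x, y, z], k=3, sampling_rate=fs, labels=("x", "y", "z"))
    indirect = float(np.mean(cond.gc["x->z"]))
    direct = min(float(np.mean(cond.gc["x->y"])), float(np.mean(cond.gc["y->z"])))
    return {
        "gc_direction_recovery_pct": float(100.0 * correct_dir / n_seeds),
        "gc_reverse_direction_mean": float(np.mean(reverse_vals)),
        "gc_integral_identity_rel_err_pct": float(100.0 * np.max(ident_errs)),
        "bic_order2_recovery_pct": float(100.0 * bic_hits / n_bic_runs),
        "gc_chain_indirect_over_direct": float(indirect / direct),
    }


def spike_phase_validation(
    rng: np.random.Generator,
    n_phases: int = 5000,
    n_null_units: int = 500,
    sampling_rate: float = 1000.0,
) -> dict:
    """Bootstrapped MRL against the von Mises closed form, Rayleigh p
    uniformity under the null, and SFC at the locking frequency."""
    out: dict = {}
    for kappa in (0.5, 1.0, 2.0, 5.0):
        ps = SpikePhaseSet(rng.vonmises(0.3, kappa, n_phases))
        target = float(special.i1(kappa) / special.i0(kappa))
        key = str(kappa).replace(".", "p")
        out[f"mrl_kappa_{key}"] = bootstrap_mrl(ps, rng=rng)
        out[f"mrl_kappa_{key}_abs_err"] = abs(out[f"mrl_kappa_{key}"] - target)
    uni = SpikePhaseSet(rng.uniform(-np.pi, np.pi, n_phases))
    out["mrl_uniform_null"] = bootstrap_mrl(uni, rng=rng)

    ps_null = [
        rayleigh(SpikePhaseSet(rng.uniform(-np.pi, np.pi, 120))).rayleigh_p
        for _ in range(n_null_units)
    ]
    _, ks_p = sstats.kstest(ps_null, "uniform")
    out["rayleigh_null_ks_p"] = float(ks_p)

    # SFC: perfectly locked spikes on an 8 Hz field vs independent spikes
    t = np.arange(0, 80.0, 1.0 / sampling_rate)
    lfp = ContinuousSignal(
        200 * np.cos(2 * np.pi * 8.0 * t) + 20 * rng.standard_normal(t.size), sampling_rate
    )
    locked = SpikeTrain(5.0 + np.arange(500) / 8.0)
    res_locked = spike_field_coherence(lfp, locked, freqs=np.array([8.0]))
    independent = SpikeTrain(np.sort(rng.uniform(5.0, 75.0, 1000)))
    res_ind = spike_field_coherence(lfp, independent)
    out["sfc_locked_at_8hz"] = float(res_locked.sfc[0])
    out["sfc_independent_max"] = float(np.nanmax(res_ind.sfc))
    return out


def behavior_validation(rng: np.random.Generator) -> dict:
    straight = gen_trajectory("straight", 100.0, 400, 0.0, seed=_seed(rng))
    idphi_straight = idphi(straight).idphi
    theta = np.linspace(0, 2 * np.pi, 300)
    loop = BehaviorTrack(10 * np.cos(theta), 10 * np.sin(theta), np.linspace(0, 6, 300))
    idphi_loop = idphi(loop).idphi
    tort = gen_trajectory("tortuous", 90.0, 250, 0.0, seed=_seed(rng))
    ang = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(ang), np.sin(ang)
    moved = BehaviorTrack(
        c * tort.x - s * tort.y + 11.0, s * tort.x + c * tort.y - 3.0, tort.t
    )
    return {
        "idphi_straight": float(idphi_straight),
        "idphi_loop_over_two_pi": float(idphi_loop / (2 * np.pi)),
        "idphi_rigid_motion_abs_diff": float(abs(idphi(moved).idphi - idphi(tort).idphi)),
        "distance_straight_100cm": float(distance_traveled(straight)),
    }


def autocorr_null(rng: np.random.Generator, n_runs: int = 20, n_points: int = 300) -> dict:
    inside = 0
    for _ in range(n_runs):
        series = CoherenceSeries(np.arange(n_points) * 0.25, rng.random(n_points))
        res = coherence_autocorr(series, n_shuffles=200, rng=rng)
        inside += res.inside_simultaneous_band()
    v = np.zeros(400)
    for i in range(1, 400):
        v[i] = 0.8 * v[i - 1] + rng.standard_normal()
    res_ar = coherence_autocorr(
        CoherenceSeries(np.arange(400) * 0.25, v), n_shuffles=300, rng=rng
    )
    return {
        "iid_inside_null_band_pct": float(100.0 * inside / n_runs),
        "ar1_lag5_autocorr": float(res_ar.autocorr[5]),
        "ar1_lag5_exceeds_null": bool(res_ar.autocorr[5] > res_ar.null_high[5]),
    }


def stats_validation(rng: np.random.Generator, n_null_sets: int = 1000) -> dict:
    bonf = tstats.bonferroni(0.0214, 2)
    bh = tstats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    rejected = 0
    for _ in range(n_null_sets):
        adj = tstats.benjamini_hochberg(rng.uniform(0, 1, 10))
        rejected += bool(np.any(adj < 0.05))
    t, _ = tstats.diff_score_ttest([0.1, 0.2, 0.3])
    return {
        "bonferroni_example": float(bonf),
        "bh_example_matches_hand_arithmetic": bool(np.allclose(bh, 0.04)),
        "bh_null_false_rejection_pct": float(100.0 * rejected / n_null_sets),
        "diff_ttest_example_t": float(t),
    }
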