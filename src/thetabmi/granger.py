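"""Directed spectral influence: Geweke Granger prediction with BIC order selection.

Granger prediction compares the residual variance of a univariate
autoregression of the target signal against the residual variance of a
bivariate autoregression that adds the source signal's past:

    time-domain GC (source→target) = log(Var[e] / Var[ε])

with e the univariate and ε the bivariate residual.  The frequency
decomposition follows Geweke: from the fitted VAR transfer function
H(ω) = (I − Σ_l A_l e^{-iωl})⁻¹ and residual covariance Σ,

    f(ω) = ln( S_tt(ω) / (S_tt(ω) − H_ts(ω) Σ_ss|t H_ts*(ω)) )

where S = HΣH* and Σ_ss|t is the source residual variance partialled on the
target residual.  The mean of f over frequency recovers the time-domain
value (Geweke's integral identity), which is asserted by test.

Pairwise-conditional GC for three sites uses the two-model approach: a full
VAR over all sites and, per source, a long-order reduced VAR over the
remaining sites solved from the model's autocovariance sequence
(block-Toeplitz Yule–Walker); the conditional spectrum is formed from
Q(ω) = Ḡ(ω)⁻¹H(ω) with the reduced inverse transfer Ḡ⁻¹ embedded over an
identity in the source slot.

All model fits are ordinary least squares on lag-stacked regressors.  When
signals arrive as epoch lists (equal-length windows), lag rows never cross
an epoch boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla


def _as_epochs(x) -> list[np.ndarray]:
    """Normalize input to a list of 1-D float epochs."""
    if isinstance(x, np.ndarray) and x.ndim == 1:
        return [np.asarray(x, dtype=float)]
    return [np.asarray(e, dtype=float) for e in x]


def _stack_rows(epochs: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag-stacked design for a multichannel AR fit, per-epoch (no rows span
    an epoch boundary).  ``epochs`` entries have shape (n_vars, T)."""
    ys, zs = [], []
    for e in epochs:
        n_vars, T = e.shape
        if T <= k:
            raise ValueError("epoch shorter than the model order")
        y = e[:, k:].T  # (T-k, n_vars)
        z = np.concatenate([e[:, k - l : T - l].T for l in range(1, k + 1)], axis=1)
        ys.append(y)
        zs.append(z)
    return np.concatenate(ys), np.concatenate(zs)


def fit_var(epochs: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS VAR(k) fit.  Returns (A, Sigma): A has shape (k, n, n) with
    x_t = Σ_l A[l] x_{t−l} + ε_t, Sigma the residual covariance (MLE
    normalization, so nested models always satisfy Var[e] ≥ Var[ε])."""
    if k < 1:
        raise ValueError("model order must be at least 1")
    for e in epochs:
        if np.ptp(e, axis=1).min() == 0:
            raise ValueError("degenerate (constant) signal")
    y, z = _stack_rows(epochs, k)
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ coef
    n_vars = y.shape[1]
    sigma = resid.T @ resid / resid.shape[0]
    A = np.stack(
        [coef[l * n_vars : (l + 1) * n_vars, :].T for l in range(k)], axis=0
    )
    return A, sigma


def spectral_radius(A: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix (stability iff < 1)."""
    k, n, _ = A.shape
    comp = np.zeros((n * k, n * k))
    comp[:n, :] = np.concatenate([A[l] for l in range(k)], axis=1)
    if k > 1:
        comp[n:, : n * (k - 1)] = np.eye(n * (k - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def var_transfer(A: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """VAR transfer function H(ω) = (I − Σ_l A_l e^{-iωl})⁻¹, shape (nf, n, n)."""
    k, n, _ = A.shape
    w = 2 * np.pi * np.asarray(freqs, dtype=float) / fs
    phases = np.exp(-1j * np.outer(w, np.arange(1, k + 1)))  # (nf, k)
    Ainv = np.eye(n)[None, :, :] - np.einsum("fl,lij->fij", phases, A)
    return np.linalg.inv(Ainv)


# ---------------------------------------------------------------------------
# Order selection


def select_order_bic(signals, max_order: int = 20) -> int:
    """Per-signal best univariate AR order by BIC, medianed across signals.

    Each candidate order is fit on the same rows (conditioning on
    ``max_order`` initial values) so BIC values are comparable; the median
    best order is rounded half away from zero.
    """
    orders = [best_order_bic(s, max_order) for s in signals]
    med = float(np.median(orders))
    return int(math.floor(med + 0.5))


def best_order_bic(signal, max_order: int = 20) -> int:
    epochs = [e[None, :] for e in _as_epochs(signal)]
    best, best_bic = 1, np.inf
    for k in range(1, max_order + 1):
        ys, zs = [], []
        for e in epochs:
            T = e.shape[1]
            if T <= max_order:
                raise ValueError("signal shorter than max_order")
            y = e[0, max_order:]
            z = np.stack([e[0, max_order - l : T - l] for l in range(1, k + 1)], axis=1)
            ys.append(y)
            zs.append(z)
        y = np.concatenate(ys)
        z = np.concatenate(zs)
        coef, *_ = np.linalg.lstsq(z, y, rcond=None)
        rss = float(np.sum((y - z @ coef) ** 2))
        n_obs = y.size
        if rss <= 0:
            continue
        bic = n_obs * math.log(rss / n_obs) + k * math.log(n_obs)
        if bic < best_bic:
            best, best_bic = k, bic
    return best


# ---------------------------------------------------------------------------
# Bivariate Geweke GC


@dataclass
class GrangerSpectrum:
    """Per-frequency directed influence for each ordered pair."""

    freqs: np.ndarray
    gc: dict[str, np.ndarray]
    time_domain_gc: dict[str, float]
    order: int
    var_uni: dict[str, float] = field(default_factory=dict)  # Var[e]
    var_biv: dict[str, float] = field(default_factory=dict)  # Var[ε]

    def spectral_mean(self, direction: str) -> float:
        return float(np.mean(self.gc[direction]))


def _partial_var(sigma: np.ndarray, src: int, rest: Sequence[int]) -> float:
    """Residual variance of the source innovation partialled on ``rest``."""
    rest = list(rest)
    s_rr = sigma[np.ix_(rest, rest)]
    s_sr = sigma[src, rest]
    return float(sigma[src, src] - s_sr @ np.linalg.solve(s_rr, s_sr))


def bivariate_gc(
    x,
    y,
    k: int,
    sampling_rate: float,
    freqs: np.ndarray | None = None,
    labels: tuple[str, str] = ("x", "y"),
) -> GrangerSpectrum:
    """Bivariate Geweke Granger prediction in both directions.

    Time-domain values come from the univariate/bivariate residual
    variances; spectral values from the VAR transfer function.  Raises if
    the fitted VAR is unstable (spectral radius ≥ 1).
    """
    ex, ey = _as_epochs(x), _as_epochs(y)
    if freqs is None:
        freqs = np.linspace(0.0, sampling_rate / 2, 256, endpoint=False)
    freqs = np.asarray(freqs, dtype=float)
    epochs = [np.stack([a, b]) for a, b in zip(ex, ey)]
    A, sigma = fit_var(epochs, k)
    rho = spectral_radius(A)
    if rho >= 1:
        raise ValueError(f"unstable VAR fit: spectral radius {rho:.4f} >= 1")
    la, lb = labels
    var_uni = {}
    for name, sig in ((la, ex), (lb, ey)):
        _, s_u = fit_var([e[None, :] for e in sig], k)
        var_uni[name] = float(s_u[0, 0])
    H = var_transfer(A, freqs, sampling_rate)
    S = np.einsum("fij,jk,flk->fil", H, sigma, H.conj())
    gc, td = {}, {}
    var_biv = {la: float(sigma[0, 0]), lb: float(sigma[1, 1])}
    for (src, tgt), (lsrc, ltgt) in (((1, 0), (lb, la)), ((0, 1), (la, lb))):
        key = f"{lsrc}->{ltgt}"
        sig_partial = _partial_var(sigma, src, [tgt])
        s_tt = np.real(S[:, tgt, tgt])
        contrib = np.real(
            H[:, tgt, src] * sig_partial * np.conj(H[:, tgt, src])
        )
        denom = np.maximum(s_tt - contrib, np.finfo(float).tiny)
        gc[key] = np.maximum(np.log(s_tt / denom), 0.0)
        ratio = var_uni[ltgt] / var_biv[ltgt]
        td[key] = float(max(np.log(ratio), 0.0))
    return GrangerSpectrum(
        freqs=freqs, gc=gc, time_domain_gc=td, order=k, var_uni=var_uni, var_biv=var_biv
    )


# ---------------------------------------------------------------------------
# Pairwise-conditional GC (three sites)


def var_autocov(A: np.ndarray, sigma: np.ndarray, n_lags: int) -> np.ndarray:
    """Autocovariance sequence G(0..n_lags) of a stable VAR, via the
    companion-form discrete Lyapunov equation and the Yule–Walker recursion."""
    k, n, _ = A.shape
    comp = np.zeros((n * k, n * k))
    comp[:n, :] = np.concatenate([A[l] for l in range(k)], axis=1)
    if k > 1:
        comp[n:, : n * (k - 1)] = np.eye(n * (k - 1))
    q = np.zeros((n * k, n * k))
    q[:n, :n] = sigma
    P = sla.solve_discrete_lyapunov(comp, q)
    G = np.zeros((n_lags + 1, n, n))
    for l in range(min(k, n_lags + 1)):
        G[l] = P[:n, l * n : (l + 1) * n]
    for l in range(k, n_lags + 1):
        G[l] = sum(A[m] @ G[l - m - 1] for m in range(k))
    return G


def _yule_walker_from_autocov(G: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve the block-Toeplitz Yule–Walker equations for a VAR(order) whose
    autocovariance sequence is G.  Returns (A, Sigma)."""
    n = G.shape[1]

    def cov(l: int) -> np.ndarray:
        return G[l] if l >= 0 else G[-l].T

    M = np.empty((order * n, order * n))
    R = np.empty((n, order * n))
    for m in range(1, order + 1):
        R[:, (m - 1) * n : m * n] = cov(m)
        for l in range(1, order + 1):
            M[(m - 1) * n : m * n, (l - 1) * n : l * n] = cov(l - m)
    # B M = R with B = [A_1 ... A_p]
    B = np.linalg.solve(M.T, R.T).T
    A = np.stack([B[:, (m - 1) * n : m * n] for m in range(1, order + 1)])
    sigma = cov(0) - sum(A[m - 1] @ cov(m).T for m in range(1, order + 1))
    sigma = (sigma + sigma.T) / 2
    return A, sigma


def _inverse_transfer(A: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Inverse transfer Ḡ(ω)⁻¹ = I − Σ_l A_l e^{-iωl}, shape (nf, n, n)."""
    k, n, _ = A.shape
    w = 2 * np.pi * np.asarray(freqs, dtype=float) / fs
    phases = np.exp(-1j * np.outer(w, np.arange(1, k + 1)))
    return np.eye(n)[None, :, :] - np.einsum("fl,lij->fij", phases, A)


def multivariate_gc(
    signals,
    k: int,
    sampling_rate: float,
    freqs: np.ndarray | None = None,
    autocov_lags: int = 200,
    reduced_order: int | None = None,
    labels: Sequence[str] = ("x", "y", "z"),
) -> GrangerSpectrum:
    """Pairwise-conditional spectral GC for three aligned sites.

    Demeaned signals are fit to a full VAR(k); its autocovariance sequence
    (out to ``autocov_lags``) yields, per source, a reduced long-order VAR
    over the remaining sites; the conditional spectrum per ordered pair is
    computed from both models.  The VAR is checked for stability and the
    autocovariance solve for positive definiteness before any GC is formed.
    """
    eps = [_as_epochs(s) for s in signals]
    n = len(eps)
    if n != 3:
        raise ValueError("multivariate_gc expects exactly 3 signals")
    if freqs is None:
        freqs = np.linspace(0.0, sampling_rate / 2, 256, endpoint=False)
    freqs = np.asarray(freqs, dtype=float)
    epochs = []
    for parts in zip(*eps):
        stacked = np.stack([p - p.mean() for p in parts])
        epochs.append(stacked)
    A, sigma = fit_var(epochs, k)
    rho = spectral_radius(A)
    if rho >= 1:
        raise ValueError(f"unstable VAR fit: spectral radius {rho:.4f} >= 1")
    G = var_autocov(A, sigma, autocov_lags)
    if np.linalg.eigvalsh(G[0]).min() <= 0:
        raise ValueError("autocovariance sequence not positive-definite")
    p_red = reduced_order if reduced_order is not None else autocov_lags
    H = var_transfer(A, freqs, sampling_rate)
    gc: dict[str, np.ndarray] = {}
    td: dict[str, float] = {}
    for j in range(n):  # source
        rest = [i for i in range(n) if i != j]
        Gr = G[:, rest][:, :, rest]
        Ar, sigma_r = _yule_walker_from_autocov(Gr, p_red)
        Ginv_r = _inverse_transfer(Ar, freqs, sampling_rate)  # (nf, 2, 2)
        # embed over identity in the source slot
        G3inv = np.zeros((freqs.size, n, n), dtype=complex)
        G3inv[:, j, j] = 1.0
        for a, ia in enumerate(rest):
            for b, ib in enumerate(rest):
                G3inv[:, ia, ib] = Ginv_r[:, a, b]
        Q = np.einsum("fij,fjk->fik", G3inv, H)
        sig_j_partial = _partial_var(sigma, j, rest)
        for a, i in enumerate(rest):  # target
            key = f"{labels[j]}->{labels[i]}"
            numer = np.real(
                np.einsum("fj,jk,fk->f", Q[:, i, :], sigma, Q[:, i, :].conj())
            )
            contrib = np.real(Q[:, i, j] * sig_j_partial * np.conj(Q[:, i, j]))
            denom = np.maximum(numer - contrib, np.finfo(float).tiny)
            gc[key] = np.maximum(np.log(np.maximum(numer, np.finfo(float).tiny) / denom), 0.0)
            td[key] = float(max(np.log(sigma_r[a, a] / sigma[i, i]), 0.0))
    return GrangerSpectrum(freqs=freqs, gc=gc, time_domain_gc=td, order=k)
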