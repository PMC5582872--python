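"""UP/DOWN detection from population spike counts with a two-state HMM.

The pooled population spike count per bin is modeled as a single point
process whose rate is modulated by a hidden two-state chain (D/U) and by the
recent firing history of the ensemble:

    y_t | s_t ~ Poisson(lambda_t),  log lambda_t = b_{s_t} + beta_h * sum_{j=1..J} y_{t-j}

with state-dependent intercepts b_D < b_U, a shared history weight beta_h
over the last J bins, and a 2x2 transition matrix. Parameters are estimated
by expectation-maximization (forward-backward E-step; exact transition
update and Newton ascent on the Poisson emission parameters in the M-step).
Per-bin UP posteriors are thresholded and adjacent same-state bins merged
into alternating U/D intervals, so transitions are resolved at the bin size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .core import PopulationSpikeData, StateIntervals, intervals_from_labels
from . import udstats

__all__ = [
    "HmmParams",
    "PosteriorTrace",
    "DetectionResult",
    "bin_counts",
    "hmm_fit",
    "decode_states",
    "detect_updown",
]


@dataclass(frozen=True)
class HmmParams:
    """History-dependent two-state HMM parameters.

    ``alpha_rate`` and ``mu_diff`` are the UP intercept and the D-U intercept
    difference on the log-rate scale (they act as EM initial values; the
    final labels, not the final parameter values, are the detection
    contract). Transition probabilities are row-stochastic.
    """

    bin_T: float = 10.0       # ms
    J_hist: int = 2
    beta_hist: float = 0.01
    P_DU: float = 0.9
    P_UD: float = 0.9
    alpha_rate: float = 3.0
    mu_diff: float = -2.0

    def __post_init__(self) -> None:
        if self.bin_T <= 0:
            raise ValueError("bin_T must be positive")
        if self.J_hist < 0:
            raise ValueError("J_hist must be non-negative")
        if not (0 < self.P_DU < 1 and 0 < self.P_UD < 1):
            raise ValueError("transition probabilities must lie in (0, 1)")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array([[1 - self.P_DU, self.P_DU], [self.P_UD, 1 - self.P_UD]])

    def with_(self, **kw) -> "HmmParams":
        return replace(self, **kw)


@dataclass
class PosteriorTrace:
    """Per-bin posterior probability of UP and the EM log-likelihood path."""

    p_up: np.ndarray
    log_likelihood: np.ndarray


@dataclass
class DetectionResult:
    intervals: StateIntervals
    params: HmmParams | None
    posterior: PosteriorTrace | None
    config: dict = field(default_factory=dict)


def bin_counts(spikes: PopulationSpikeData, bin_T: float = 10.0) -> np.ndarray:
    """Merged-population spike counts per bin of ``bin_T`` ms."""
    if bin_T <= 0:
        raise ValueError("bin_T must be positive")
    dt = bin_T / 1000.0
    n_bins = max(int(np.ceil(spikes.duration / dt)), 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    merged = spikes.merged()
    if merged.size:
        idx = np.clip((merged / dt).astype(np.int64), 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return counts


@njit(cache=True)
def _forward_backward(log_e, P, pi):  # pragma: no cover - jitted
    """Scaled forward-backward. Returns gamma, xi_sum, loglik."""
    T = log_e.shape[0]
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    c = np.empty(T)
    # emission probabilities, renormalized rowwise for stability
    e = np.empty((T, 2))
    for t in range(T):
        m = max(log_e[t, 0], log_e[t, 1])
        e[t, 0] = np.exp(log_e[t, 0] - m)
        e[t, 1] = np.exp(log_e[t, 1] - m)
        c[t] = m  # stash the shift; scaling factors handled below
    loglik = 0.0
    s = 0.0
    for j in range(2):
        alpha[0, j] = pi[j] * e[0, j]
        s += alpha[0, j]
    alpha[0, 0] /= s
    alpha[0, 1] /= s
    loglik += np.log(s) + c[0]
    scale = np.empty(T)
    scale[0] = s
    for t in range(1, T):
        s = 0.0
        for j in range(2):
            a = alpha[t - 1, 0] * P[0, j] + alpha[t - 1, 1] * P[1, j]
            alpha[t, j] = a * e[t, j]
            s += alpha[t, j]
        alpha[t, 0] /= s
        alpha[t, 1] /= s
        scale[t] = s
        loglik += np.log(s) + c[t]
    beta[T - 1, 0] = 1.0
    beta[T - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        for i in range(2):
            beta[t, i] = (
                P[i, 0] * e[t + 1, 0] * beta[t + 1, 0]
                + P[i, 1] * e[t + 1, 1] * beta[t + 1, 1]
            ) / scale[t + 1]
        denom = 0.0
        for i in range(2):
            for j in range(2):
                denom += alpha[t, i] * P[i, j] * e[t + 1, j] * beta[t + 1, j]
        for i in range(2):
            for j in range(2):
                xi[i, j] += alpha[t, i] * P[i, j] * e[t + 1, j] * beta[t + 1, j] / denom
    gamma = alpha * beta
    for t in range(T):
        s = gamma[t, 0] + gamma[t, 1]
        gamma[t, 0] /= s
        gamma[t, 1] /= s
    return gamma, xi, loglik


def _history(counts: np.ndarray, J: int) -> np.ndarray:
    """Sum of the previous J counts per bin (partial sums near the start)."""
    h = np.zeros(counts.size)
    for j in range(1, J + 1):
        h[j:] += counts[:-j]
    return h


def _emission_loglik(counts, h, b, beta_h):
    eta = np.clip(b[None, :] + beta_h * h[:, None], -30.0, 30.0)
    lam = np.exp(eta)
    # log Poisson pmf up to the y! term (constant in parameters)
    return counts[:, None] * eta - lam, lam, eta


def hmm_fit(
    counts: np.ndarray,
    init: HmmParams | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[HmmParams, PosteriorTrace]:
    """Fit the history-dependent two-state HMM by EM.

    Returns the fitted parameters and the posterior trace at convergence
    (|delta loglik| < ``tol``). The fit is canonicalized so the
    higher-emission state is UP. All-zero counts yield a degenerate single-D
    labeling with a warning.
    """
    init = init or HmmParams()
    counts = np.asarray(counts, dtype=np.int64)
    if counts.size <= init.J_hist:
        raise ValueError("counts length must exceed the history order")
    if counts.max() == 0:
        warnings.warn("all-zero counts: returning a single DOWN state")
        return init, PosteriorTrace(p_up=np.zeros(counts.size), log_likelihood=np.array([]))

    h = _history(counts, init.J_hist)
    b = np.array([init.alpha_rate + init.mu_diff, init.alpha_rate], dtype=float)
    beta_h = float(init.beta_hist) if init.J_hist > 0 else 0.0
    P = init.transition_matrix.copy()
    pi = np.array([0.5, 0.5])
    y = counts.astype(float)

    logliks = []
    for _ in range(max_iter):
        log_e, lam, _ = _emission_loglik(counts, h, b, beta_h)
        gamma, xi, ll = _forward_backward(log_e, P, pi)
        logliks.append(ll)
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            break
        # M-step: transitions and initial distribution
        P = xi / np.maximum(xi.sum(axis=1, keepdims=True), 1e-300)
        pi = np.maximum(gamma[0], 1e-12)
        pi = pi / pi.sum()
        # M-step: Newton ascent on (b_D, b_U[, beta_h]) with step halving
        b, beta_h = _emission_mstep(y, h, gamma, b, beta_h, fit_beta=init.J_hist > 0)

    log_e, _, _ = _emission_loglik(counts, h, b, beta_h)
    gamma, _, ll = _forward_backward(log_e, P, pi)
    # canonicalize: state 1 = UP = higher intercept
    if b[0] > b[1]:
        b = b[::-1].copy()
        P = P[::-1, ::-1].copy()
        gamma = gamma[:, ::-1].copy()
    fitted = init.with_(
        alpha_rate=float(b[1]),
        mu_diff=float(b[0] - b[1]),
        beta_hist=float(beta_h),
        P_DU=float(np.clip(P[0, 1], 1e-6, 1 - 1e-6)),
        P_UD=float(np.clip(P[1, 0], 1e-6, 1 - 1e-6)),
    )
    return fitted, PosteriorTrace(p_up=gamma[:, 1], log_likelihood=np.array(logliks))


def _emission_mstep(y, h, gamma, b, beta_h, fit_beta, n_newton=4):
    def q_value(b_, beta_):
        eta = np.clip(b_[None, :] + beta_ * h[:, None], -30.0, 30.0)
        return float(np.sum(gamma * (y[:, None] * eta - np.exp(eta))))

    for _ in range(n_newton):
        eta = np.clip(b[None, :] + beta_h * h[:, None], -30.0, 30.0)
        lam = np.exp(eta)
        resid = y[:, None] - lam
        g_b = np.sum(gamma * resid, axis=0)
        if fit_beta:
            g_beta = np.sum(gamma * resid * h[:, None])
            grad = np.array([g_b[0], g_b[1], g_beta])
            H = np.zeros((3, 3))
            H[0, 0] = -np.sum(gamma[:, 0] * lam[:, 0])
            H[1, 1] = -np.sum(gamma[:, 1] * lam[:, 1])
            H[0, 2] = H[2, 0] = -np.sum(gamma[:, 0] * lam[:, 0] * h)
            H[1, 2] = H[2, 1] = -np.sum(gamma[:, 1] * lam[:, 1] * h)
            H[2, 2] = -np.sum(gamma * lam * (h * h)[:, None])
        else:
            grad = g_b
            H = np.diag([-np.sum(gamma[:, 0] * lam[:, 0]), -np.sum(gamma[:, 1] * lam[:, 1])])
        try:
            step = np.linalg.solve(H - 1e-9 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError:
            break
        q0 = q_value(b, beta_h)
        scale = 1.0
        for _ in range(20):
            b_new = b - scale * (step[:2])
            beta_new = beta_h - scale * step[2] if fit_beta else beta_h
            if q_value(b_new, beta_new) >= q0:
                b, beta_h = b_new, beta_new
                break
            scale *= 0.5
        else:
            break
    return b, beta_h


def decode_states(
    counts: np.ndarray,
    params: HmmParams,
    posterior: PosteriorTrace,
    threshold: float = 0.5,
    min_dur: float = 0.0,
) -> StateIntervals:
    """Posterior thresholding -> per-bin labels -> merged alternating intervals.

    Transition times sit on bin edges, so the time resolution is the bin
    size. Runs shorter than ``min_dur`` ms are absorbed into neighbors.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    labels = posterior.p_up > threshold
    dt = params.bin_T / 1000.0
    edges = np.arange(counts.size + 1) * dt
    return intervals_from_labels(labels, edges, min_duration_s=min_dur / 1000.0)


def detect_updown(spikes: PopulationSpikeData, config: dict | None = None) -> DetectionResult:
    """End-to-end U/D detection pipeline: bin -> fit -> decode.

    ``config`` selects the detector: ``{"method": "hmm", ...}`` (default,
    keys matching :class:`HmmParams` plus ``threshold`` and ``min_dur_ms``)
    or ``{"method": "threshold", "rate_threshold_hz": ..., "kernel_ms": ...,
    "min_dur_ms": ...}`` on the square-kernel population rate.
    """
    config = dict(config or {})
    method = config.get("method", "hmm")
    if method == "hmm":
        hp_keys = {k: v for k, v in config.items()
                   if k in HmmParams.__dataclass_fields__}
        init = HmmParams(**hp_keys)
        counts = bin_counts(spikes, init.bin_T)
        fitted, post = hmm_fit(counts, init,
                               max_iter=config.get("max_iter", 100),
                               tol=config.get("tol", 1e-6))
        intervals = decode_states(
            counts, fitted, post,
            threshold=config.get("threshold", 0.5),
            min_dur=config.get("min_dur_ms", 0.0),
        )
        return DetectionResult(intervals=intervals, params=fitted, posterior=post,
                               config={**config, "method": "hmm"})
    if method == "threshold":
        kernel = config.get("kernel_ms", 50.0)
        thr = config.get("rate_threshold_hz", 1.0)
        t, R = udstats.population_rate(spikes, kernel_T=kernel, dt_ms=1.0)
        dt_s = 0.001
        edges = np.concatenate((t - 0.5 * dt_s, [t[-1] + 0.5 * dt_s]))
        intervals = intervals_from_labels(
            R >= thr, edges, min_duration_s=config.get("min_dur_ms", 50.0) / 1000.0
        )
        return DetectionResult(intervals=intervals, params=None, posterior=None,
                               config={**config, "method": "threshold"})
    raise ValueError(f"unknown detector method: {method!r}")
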