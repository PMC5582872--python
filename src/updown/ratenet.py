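"""Two-population rate model with spike-frequency adaptation and OU input noise.

The model describes the mean instantaneous rates r_E and r_I of a recurrently
coupled excitatory-inhibitory network. The E population carries an additive
adaptation current a(t) growing linearly with r_E:

    tau_E dr_E/dt = -r_E + phi_E(J_EE r_E - J_EI r_I - a + sigma xi_E)
    tau_I dr_I/dt = -r_I + phi_I(J_IE r_E - J_II r_I + sigma xi_I)
    tau_a da/dt   = -a + beta r_E

with threshold-linear transfer functions phi_X(x) = g_X [x - theta_X]_+ and
two independent zero-mean Ornstein-Uhlenbeck processes xi_E, xi_I.
Integration is fourth-order Runge-Kutta; the OU inputs are advanced by exact
discretization and held constant within each RK4 step, so their stationary SD
equals sigma for any step size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .core import StateIntervals, intervals_from_labels

__all__ = [
    "RateModelParams",
    "RateTrajectory",
    "transfer",
    "ou_noise",
    "simulate_rate",
    "detect_states_threshold",
    "GREEN_SQUARE",
    "DEFAULT_PARAMS",
]


@dataclass(frozen=True)
class RateModelParams:
    """Parameters of the EI rate model.

    Time constants in ms; couplings ``J_XY`` in seconds (weight x time, so that
    ``J * r`` with r in Hz is a dimensionless input); gains in Hz per input
    unit; thresholds and sigma in input units (a.u.).
    """

    tau_E: float = 10.0
    tau_I: float = 2.0
    tau_a: float = 500.0
    J_EE: float = 5.0
    J_EI: float = 1.0
    J_IE: float = 10.0
    J_II: float = 0.5
    beta_adapt: float = 0.5
    g_E: float = 1.0
    g_I: float = 4.0
    theta_E: float = 4.8
    theta_I: float = 25.0
    sigma_noise: float = 3.5
    tau_ou: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_E", "tau_I", "tau_a", "tau_ou"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("J_EE", "J_EI", "J_IE", "J_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (signs live in the equations)")
        if self.g_E <= 0 or self.g_I <= 0:
            raise ValueError("gains must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")

    def with_(self, **kw) -> "RateModelParams":
        return replace(self, **kw)


#: Default parameter set (Methods values, beta = 0.5 s).
DEFAULT_PARAMS = RateModelParams()

#: The fitted example point of the regime map (theta_E = 4.8 a.u.,
#: beta = 0.7 Hz^-1) used for the quantitative comparisons with data.
GREEN_SQUARE = RateModelParams(beta_adapt=0.7)


@dataclass
class RateTrajectory:
    """Simulated (r_E, r_I, a) time series on a uniform grid (seconds)."""

    time: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    a: np.ndarray
    dt_ms: float
    noise_E: np.ndarray | None = None
    noise_I: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.time, "r_E_hz": self.r_E, "r_I_hz": self.r_I, "a_au": self.a}
        )


def transfer(x, gain: float, threshold: float):
    """Threshold-linear transfer ``g [x - theta]_+``.

    Continuous, piecewise-linear and non-negative; output is exactly 0 at the
    kink ``x == theta``.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to transfer function")
    out = gain * np.maximum(x - threshold, 0.0)
    return out if out.ndim else float(out)


def ou_noise(
    tau_ou: float,
    sigma: float,
    dt: float,
    n_steps: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stationary zero-mean Ornstein-Uhlenbeck series by exact discretization.

    The update ``x[n+1] = rho x[n] + sigma sqrt(1 - rho^2) N(0,1)`` with
    ``rho = exp(-dt/tau_ou)`` has stationary SD exactly ``sigma`` regardless of
    ``dt`` and autocorrelation time ``tau_ou``. The series starts from a draw
    of the stationary law. Times in ms.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tau_ou <= 0:
        raise ValueError("tau_ou must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if sigma == 0:
        return np.zeros(n_steps)
    rho = np.exp(-dt / tau_ou)
    innov_sd = sigma * np.sqrt(1.0 - rho * rho)
    x = np.empty(n_steps)
    white = rng.standard_normal(n_steps)
    _ou_fill(x, white, rho, innov_sd, sigma)
    return x


@njit(cache=True)
def _ou_fill(x, white, rho, innov_sd, sigma):  # pragma: no cover - jitted
    x[0] = sigma * white[0]
    for n in range(1, x.size):
        x[n] = rho * x[n - 1] + innov_sd * white[n]


@njit(cache=True, inline="always")
def _derivs(ee, ii, aa, xe, xi, tauE, tauI, tauA,
            JEE, JEI, JIE, JII, beta, gE, gI, thE, thI):  # pragma: no cover
    ue = JEE * ee - JEI * ii - aa + xe - thE
    fe = gE * ue if ue > 0.0 else 0.0
    ui = JIE * ee - JII * ii + xi - thI
    fi = gI * ui if ui > 0.0 else 0.0
    return (-ee + fe) / tauE, (-ii + fi) / tauI, (-aa + beta * ee) / tauA


@njit(cache=True)
def _rk4_loop(
    rE, rI, a, xiE, xiI,
    tauE, tauI, tauA, JEE, JEI, JIE, JII, beta, gE, gI, thE, thI, dt,
):  # pragma: no cover - jitted
    n = rE.size
    for k in range(n - 1):
        e = rE[k]
        i = rI[k]
        ad = a[k]
        xe = xiE[k]
        xi = xiI[k]
        # RK4 with noise held constant over the step
        k1e, k1i, k1a = _derivs(e, i, ad, xe, xi, tauE, tauI, tauA,
                                JEE, JEI, JIE, JII, beta, gE, gI, thE, thI)
        k2e, k2i, k2a = _derivs(e + 0.5 * dt * k1e, i + 0.5 * dt * k1i,
                                ad + 0.5 * dt * k1a, xe, xi, tauE, tauI, tauA,
                                JEE, JEI, JIE, JII, beta, gE, gI, thE, thI)
        k3e, k3i, k3a = _derivs(e + 0.5 * dt * k2e, i + 0.5 * dt * k2i,
                                ad + 0.5 * dt * k2a, xe, xi, tauE, tauI, tauA,
                                JEE, JEI, JIE, JII, beta, gE, gI, thE, thI)
        k4e, k4i, k4a = _derivs(e + dt * k3e, i + dt * k3i,
                                ad + dt * k3a, xe, xi, tauE, tauI, tauA,
                                JEE, JEI, JIE, JII, beta, gE, gI, thE, thI)
        rE[k + 1] = e + dt / 6.0 * (k1e + 2 * k2e + 2 * k3e + k4e)
        rI[k + 1] = i + dt / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
        a[k + 1] = ad + dt / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
        if rE[k + 1] < 0.0:
            rE[k + 1] = 0.0
        if rI[k + 1] < 0.0:
            rI[k + 1] = 0.0
        if not (np.isfinite(rE[k + 1]) and np.isfinite(rI[k + 1]) and np.isfinite(a[k + 1])):
            return k + 1
    return -1


def simulate_rate(
    params: RateModelParams,
    duration: float,
    dt: float = 0.2,
    init: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int | np.random.Generator = 0,
    keep_noise: bool = False,
) -> RateTrajectory:
    """Integrate the rate model with RK4.

    Parameters
    ----------
    duration
        Simulated time in seconds.
    dt
        Integration step in ms (default 0.2 ms).
    init
        Initial ``(r_E, r_I, a)``; components must be non-negative.
    seed
        Seed (or Generator) for the two OU input processes.

    Notes
    -----
    With ``sigma_noise = 0`` the trajectory is deterministic and reproducible
    bit-for-bit for a given ``dt``. Rates are clipped at 0, consistent with
    the rectifying transfer function.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if any(v < 0 for v in init):
        raise ValueError("init components must be non-negative")
    n_steps = int(round(duration * 1000.0 / dt)) + 1
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xiE = ou_noise(params.tau_ou, params.sigma_noise, dt, n_steps, rng)
    xiI = ou_noise(params.tau_ou, params.sigma_noise, dt, n_steps, rng)
    rE = np.empty(n_steps)
    rI = np.empty(n_steps)
    a = np.empty(n_steps)
    rE[0], rI[0], a[0] = init
    bad = _rk4_loop(
        rE, rI, a, xiE, xiI,
        params.tau_E, params.tau_I, params.tau_a,
        params.J_EE, params.J_EI, params.J_IE, params.J_II,
        params.beta_adapt, params.g_E, params.g_I,
        params.theta_E, params.theta_I, dt,
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite state at integration step {bad}")
    time = np.arange(n_steps) * (dt / 1000.0)
    return RateTrajectory(
        time=time, r_E=rE, r_I=rI, a=a, dt_ms=dt,
        noise_E=xiE if keep_noise else None,
        noise_I=xiI if keep_noise else None,
    )


def detect_states_threshold(
    trace: RateTrajectory, threshold: float = 1.0, min_duration: float = 50.0
) -> StateIntervals:
    """Detect model U/D states by thresholding r_E.

    Bins with ``r_E >= threshold`` (Hz) are UP; runs shorter than
    ``min_duration`` (ms) are merged into their neighbors, iterated to a fixed
    point.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if trace.r_E.size == 0:
        raise ValueError("empty trace")
    labels = trace.r_E >= threshold
    dt_s = trace.dt_ms / 1000.0
    edges = np.concatenate((trace.time, [trace.time[-1] + dt_s]))
    return intervals_from_labels(labels, edges, min_duration_s=min_duration / 1000.0)
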