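"""Analytic phase-plane machinery for the EI rate model.

Because the rates evolve much faster than adaptation (tau_E, tau_I << tau_a),
the 3-D system splits into fast 2-D rate dynamics at frozen adaptation and a
slow drift of a(t) along the rate fixed points. All closed forms below follow
from that separation of time scales.

With J'_EE = J_EE - 1/g_E and J'_II = J_II + 1/g_I, the UP fixed point at
adaptation equilibrium a = beta r_E is

    r_E* = (J_EI theta_I - J'_II theta_E) / |M|
    r_I* = ((J'_EE - beta) theta_I - J_IE theta_E) / |M|
    |M|  = J_EI J_IE - (J'_EE - beta) J'_II

and the DOWN point (0, 0, 0) exists iff theta_E >= 0, theta_I >= 0 and is
stable iff theta_E > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import udstats
from .ratenet import RateModelParams, detect_states_threshold, simulate_rate

__all__ = [
    "FixedPointSet",
    "RegimeLabel",
    "nullclines",
    "fixed_points",
    "is_inhibition_stabilized",
    "classify_regime",
    "regime_map",
    "sweep_statistics",
]


class RegimeLabel(str, Enum):
    """Dynamical regime of the model at a given (theta_E, beta) point."""

    D_ONLY = "D_only"
    U_ONLY = "U_only"
    BISTABLE = "bistable_metastable"
    D_META_U_QUASI = "D_meta_U_quasi"
    U_META_D_QUASI = "U_meta_D_quasi"
    OSCILLATORY = "oscillatory_quasi_quasi"


@dataclass
class FixedPointSet:
    """Fixed points of the rate model with existence/stability flags."""

    d_exists: bool
    d_stable: bool
    u_exists: bool
    u_stable: bool
    u_rE: float
    u_rI: float
    u_a: float
    J_EE_eff: float
    J_II_eff: float
    det_M: float


def _effective(params: RateModelParams) -> tuple[float, float]:
    return params.J_EE - 1.0 / params.g_E, params.J_II + 1.0 / params.g_I


def _rate_stability(params: RateModelParams) -> tuple[bool, bool]:
    """Determinant/trace conditions for stability of the interior fixed point
    of the fast 2-D rate dynamics (adaptation frozen)."""
    Jee, Jii = _effective(params)
    det_ok = Jii * Jee < params.J_EI * params.J_IE
    trace_ok = params.tau_I * (params.g_E * params.J_EE + 1) < params.tau_E * (
        params.g_I * params.J_II + 1
    )
    return det_ok, trace_ok


def nullclines(
    params: RateModelParams, a_fixed: float = 0.0, r_E_grid: np.ndarray | None = None
):
    """E- and I-nullclines of the fast 2-D system in the (r_E, r_I) plane.

    Returns ``(r_E_grid, rI_on_E_nullcline, rI_on_I_nullcline)``. The
    E-nullcline shifts downward as ``a_fixed`` increases; the I-nullcline does
    not depend on adaptation.

    On the E-nullcline, r_E = g_E [J_EE r_E - J_EI r_I - a - theta_E]_+ gives
    r_I = (J'_EE r_E - a - theta_E) / J_EI wherever r_E > 0. On the
    I-nullcline, r_I = g_I [J_IE r_E - J_II r_I - theta_I]_+ gives
    r_I = (J_IE r_E - theta_I) / J'_II (clipped at 0).
    """
    if r_E_grid is None:
        r_E_grid = np.linspace(0.0, 10.0, 501)
    Jee, Jii = _effective(params)
    e_null = (Jee * r_E_grid - a_fixed - params.theta_E) / params.J_EI
    i_null = np.maximum((params.J_IE * r_E_grid - params.theta_I) / Jii, 0.0)
    return r_E_grid, e_null, i_null


def fixed_points(params: RateModelParams) -> FixedPointSet:
    """Analytic fixed points with existence and stability flags.

    The UP point is evaluated at adaptation equilibrium ``a = beta r_E``. UP
    existence requires a positive r_I numerator (given stability, r_E > 0
    follows); UP stability requires in addition the determinant and trace
    conditions of the fast subsystem.
    """
    Jee, Jii = _effective(params)
    beta = params.beta_adapt
    detM = params.J_EI * params.J_IE - (Jee - beta) * Jii
    d_exists = params.theta_E >= 0 and params.theta_I >= 0
    d_stable = d_exists and params.theta_E > 0

    det_ok, trace_ok = _rate_stability(params)
    # U existence: r_I numerator positive (Eq-20 equivalent form)
    num_rI = (Jee - beta) * params.theta_I - params.J_IE * params.theta_E
    u_exists = num_rI > 0
    if u_exists and detM <= 0 and det_ok:
        raise ArithmeticError("inconsistent fixed-point structure: |M| <= 0 with stable couplings")
    if u_exists and detM > 0:
        rE = (params.J_EI * params.theta_I - Jii * params.theta_E) / detM
        rI = num_rI / detM
        u_exists = rE > 0 and rI > 0
    else:
        rE = rI = np.nan
        u_exists = False
    u_stable = bool(u_exists and det_ok and trace_ok)
    return FixedPointSet(
        d_exists=d_exists,
        d_stable=d_stable,
        u_exists=bool(u_exists),
        u_stable=u_stable,
        u_rE=float(rE),
        u_rI=float(rI),
        u_a=float(beta * rE) if u_exists else np.nan,
        J_EE_eff=Jee,
        J_II_eff=Jii,
        det_M=detM,
    )


def is_inhibition_stabilized(params: RateModelParams) -> bool:
    """Whether the UP state is an inhibition-stabilized network (ISN) state.

    True iff the E subnetwork alone is unstable at frozen inhibition
    (J'_EE > 0) while the full fixed point satisfies the determinant and trace
    stability conditions. The flag refers to the fast rate dynamics at frozen
    adaptation, so beta does not enter.
    """
    fps = fixed_points(params)
    if not fps.u_exists:
        raise ValueError("ISN check requires an existing UP fixed point")
    det_ok, trace_ok = _rate_stability(params)
    return fps.J_EE_eff > 0 and det_ok and trace_ok


def classify_regime(params: RateModelParams) -> RegimeLabel:
    """Partition of the (theta_E, beta) plane into the six dynamical regimes.

    Boundary convention: non-strict inequalities resolve to the "more stable"
    label (equality on the U-stability boundary counts as U stable; equality
    on the adaptation-balance boundary of the mixed U/D region counts as
    U_only).
    """
    det_ok, trace_ok = _rate_stability(params)
    if not (det_ok and trace_ok):
        raise ValueError("couplings must satisfy the fast-subsystem stability conditions")
    Jee, Jii = _effective(params)
    thE, thI = params.theta_E, params.theta_I
    beta = params.beta_adapt
    d_stable = thE > 0
    # U stable (adaptation included): beta <= J'_EE - J_IE theta_E / theta_I
    beta_u = Jee - params.J_IE * thE / thI
    u_stable = beta <= beta_u
    # U exists at beta = 0: theta_E < J'_EE theta_I / J_IE
    u_exists_beta0 = thE < Jee * thI / params.J_IE
    if d_stable and u_stable:
        return RegimeLabel.BISTABLE
    if d_stable and not u_stable:
        return RegimeLabel.D_META_U_QUASI if u_exists_beta0 else RegimeLabel.D_ONLY
    if u_stable:
        # theta_E <= 0: D is at best quasi-stable, held transiently by the
        # adaptation recruited in U: beta > slope * theta_E with
        # slope = (J'_EE J'_II - J_IE J_EI) / (J_EI theta_I) (negative).
        slope = (Jee * Jii - params.J_IE * params.J_EI) / (params.J_EI * thI)
        return RegimeLabel.U_META_D_QUASI if beta > slope * thE else RegimeLabel.U_ONLY
    return RegimeLabel.OSCILLATORY


def regime_map(
    params: RateModelParams, theta_E_grid: np.ndarray, beta_grid: np.ndarray
) -> np.ndarray:
    """Regime label for every (theta_E, beta) grid point.

    Returns an object array of shape ``(len(beta_grid), len(theta_E_grid))``
    of :class:`RegimeLabel` values (rows index beta).
    """
    out = np.empty((len(beta_grid), len(theta_E_grid)), dtype=object)
    for i, beta in enumerate(beta_grid):
        for j, thE in enumerate(theta_E_grid):
            out[i, j] = classify_regime(params.with_(theta_E=thE, beta_adapt=beta))
    return out


def sweep_statistics(
    params: RateModelParams,
    theta_E_grid: np.ndarray,
    beta_grid: np.ndarray,
    sigma: float = 3.5,
    duration: float = 100.0,
    seed: int = 0,
    min_periods: int = 20,
    dt: float = 0.2,
):
    """Simulated U/D statistics over a (theta_E, beta) grid.

    For each grid point runs :func:`~updown.ratenet.simulate_rate`, detects
    states by thresholding and computes mean, CV and the lag-0/lag-1 duration
    correlations. Points with fewer than ``min_periods`` complete periods are
    reported as NaN (too few transitions).

    Returns a dict of 2-D arrays keyed by
    ``mean_U, mean_D, cv_U, cv_D, corr_UD_lag0, corr_UD_lag1``.
    """
    if sigma <= 0:
        raise ValueError("sweep requires sigma > 0")
    keys = ("mean_U", "mean_D", "cv_U", "cv_D", "corr_UD_lag0", "corr_UD_lag1")
    shape = (len(beta_grid), len(theta_E_grid))
    out = {k: np.full(shape, np.nan) for k in keys}
    rng = np.random.default_rng(seed)
    for i, beta in enumerate(beta_grid):
        for j, thE in enumerate(theta_E_grid):
            p = params.with_(theta_E=thE, beta_adapt=beta, sigma_noise=sigma)
            traj = simulate_rate(p, duration, dt=dt, seed=rng.integers(2**31))
            try:
                iv = detect_states_threshold(traj)
                seqs = udstats.durations(iv)
            except ValueError:
                continue
            if min(len(seqs.U), len(seqs.D)) < min_periods:
                continue
            out["mean_U"][i, j] = float(np.mean(seqs.U))
            out["mean_D"][i, j] = float(np.mean(seqs.D))
            out["cv_U"][i, j] = udstats.duration_stats(seqs.U).cv
            out["cv_D"][i, j] = udstats.duration_stats(seqs.D).cv
            n = min(len(seqs.U), len(seqs.D))
            out["corr_UD_lag0"][i, j] = _pearson(seqs.U[:n], seqs.D[:n])
            if n > 2:
                out["corr_UD_lag1"][i, j] = _pearson(seqs.U[: n - 1], seqs.D[1:n])
    return out


def _pearson(x, y) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])
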