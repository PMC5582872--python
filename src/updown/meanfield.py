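"""Self-consistent mean-field analysis of the spiking EI network.

The equilibrium rate of an LIF neuron receiving white-noise input with mean
mu and SD sigma is the first-passage (Ricciardi) rate

    r0 = [ tau_m sqrt(pi) * Integral_{(Vr-mu)/sigma}^{(theta-mu)/sigma}
           erfcx(-u) du ]^-1

where erfcx(-u) = e^{u^2} erfc(-u) is the numerically benign form of the
classic double integral. The population fixed points solve the 2-D
self-consistency r_X = r0(mu_X(r_E, r_I)) with

    mu_E = V_L + depol_E + N_E J_EE r_E tau_u + N_I J_EI r_I tau_u - Ia
    mu_I = V_L + depol_I + N_E J_IE r_E tau_u + N_I J_II r_I tau_u

(the AHP current Ia frozen as a control parameter) and the input SD given by
the external white-noise sigma alone, as appropriate for all-to-all coupling
where recurrent input fluctuations are non-extensive. Stability is assessed
from the Jacobian of the rate relaxation map damped with the membrane time
constants; folds are additionally located by branch termination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize
from scipy.special import erfcx

from .spikenet import SpikingNetParams

__all__ = [
    "MeanFieldPoint",
    "MeanFieldBranch",
    "lif_rate",
    "mean_inputs",
    "self_consistent_rates",
    "bifurcation_scan",
    "ahp_equilibrium",
]


def ahp_equilibrium(params, r_E: float) -> float:
    """Equilibrium population AHP current (mV) at E rate ``r_E`` (Hz).

    Each spike adds beta_ahp / tau_a to Ia which decays with tau_a, so the
    stationary mean is beta_ahp (mV*ms) times the rate (spikes/ms).
    """
    return params.beta_ahp * r_E / 1000.0

_ASYMPTOTIC_EDGE = 15.0


@dataclass
class MeanFieldPoint:
    """Self-consistent equilibrium of the population rates at frozen Ia."""

    r_E: float
    r_I: float
    mu_E: float
    mu_I: float
    sigma: float
    Ia: float
    stable: bool
    converged: bool


@dataclass
class MeanFieldBranch:
    """One solution branch along an Ia sweep (constant stability flag)."""

    name: str
    Ia: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    stable: bool


def lif_rate(mu: float, sigma: float, tau_m: float, V_r: float, theta: float) -> float:
    """First-passage firing rate (Hz) of an LIF neuron.

    Parameters: mean input ``mu`` and input SD ``sigma`` in mV, membrane time
    constant ``tau_m`` in ms, reset ``V_r`` and threshold ``theta`` in mV.
    Stable for threshold distances up to tens of SDs via an asymptotic form.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive (deterministic limit not implemented)")
    tau_s = tau_m / 1000.0
    a = (V_r - mu) / sigma
    b = (theta - mu) / sigma
    if b > _ASYMPTOTIC_EDGE:
        # Laplace asymptotics of the outer integral: int ~ e^{b^2}/b - e^{a^2}/a
        log_int = b * b - np.log(b)
        if a > 1.0:
            log_int += np.log1p(-np.exp(a * a - np.log(a) - log_int))
        log_r = -np.log(tau_s * np.sqrt(np.pi)) - log_int
        return float(np.exp(log_r))
    val, _ = integrate.quad(lambda u: erfcx(-u), a, b, epsabs=1e-12, epsrel=1e-10, limit=200)
    return float(1.0 / (tau_s * np.sqrt(np.pi) * val))


def mean_inputs(
    params: SpikingNetParams, r_E: float, r_I: float, Ia: float = 0.0
) -> tuple[float, float]:
    """Mean input currents (mu_E, mu_I) in mV at given population rates (Hz)."""
    tau_u = params.tau_unit / 1000.0
    mu_E = (
        params.V_L + params.depol_E
        + params.N_E * params.J_EE * r_E * tau_u
        + params.N_I * params.J_EI * r_I * tau_u
        - Ia
    )
    mu_I = (
        params.V_L + params.depol_I
        + params.N_E * params.J_IE * r_E * tau_u
        + params.N_I * params.J_II * r_I * tau_u
    )
    return mu_E, mu_I


def _rate_map(params: SpikingNetParams, r: np.ndarray, Ia: float) -> np.ndarray:
    mu_E, mu_I = mean_inputs(params, r[0], r[1], Ia)
    # sigma_white parameterizes the free-membrane voltage SD; the transfer
    # function's sigma is the corresponding diffusion amplitude (factor
    # sqrt(2)), so both routes describe the same physical noise
    s = np.sqrt(2.0) * params.sigma_white
    return np.array([
        lif_rate(mu_E, s, params.tau_E, params.V_r_E, params.theta_spk_E),
        lif_rate(mu_I, s, params.tau_I, params.V_r_I, params.theta_spk_I),
    ])


def self_consistent_rates(
    params: SpikingNetParams,
    Ia: float = 0.0,
    init: tuple[float, float] = (0.0, 0.0),
    tol: float = 1e-8,
) -> MeanFieldPoint:
    """Solve the 2-D rate self-consistency at frozen AHP current.

    Non-convergence is reported through the ``converged`` flag rather than an
    exception. Stability comes from the eigenvalues of the Jacobian of the
    relaxation dynamics ``tau_X dr_X/dt = -r_X + F_X(r)``.
    """
    def G(r):
        return _rate_map(params, np.maximum(r, 0.0), Ia) - np.maximum(r, 0.0)

    sol = optimize.root(G, np.asarray(init, dtype=float), method="hybr", tol=1e-12)
    r = np.maximum(sol.x, 0.0)
    converged = bool(sol.success and np.max(np.abs(G(r))) < tol)
    mu_E, mu_I = mean_inputs(params, r[0], r[1], Ia)
    stable = _is_stable(params, r, Ia) if converged else False
    return MeanFieldPoint(
        r_E=float(r[0]), r_I=float(r[1]), mu_E=mu_E, mu_I=mu_I,
        sigma=float(np.sqrt(2.0) * params.sigma_white), Ia=Ia,
        stable=stable, converged=converged,
    )


def _is_stable(params: SpikingNetParams, r: np.ndarray, Ia: float) -> bool:
    h = 1e-5 + 1e-5 * np.abs(r)
    J = np.empty((2, 2))
    for j in range(2):
        rp = r.copy()
        rm = r.copy()
        rp[j] += h[j]
        rm[j] = max(rm[j] - h[j], 0.0)
        J[:, j] = (_rate_map(params, rp, Ia) - _rate_map(params, rm, Ia)) / (rp[j] - rm[j])
    taus = np.array([params.tau_E, params.tau_I]) / 1000.0
    A = (J - np.eye(2)) / taus[:, None]
    return bool(np.all(np.linalg.eigvals(A).real < 0))


def bifurcation_scan(params: SpikingNetParams, Ia_grid) -> dict:
    """Trace the quiescent, UP and unstable solution branches over an Ia grid.

    For each grid value the self-consistency is solved from several initial
    guesses (quiescent, low-rate, high-rate and continuation from the
    neighboring grid point); distinct roots are classified by rate and
    stability. Returns a dict with ``branches`` (list of
    :class:`MeanFieldBranch`) and ``saddle_nodes`` (Ia values where the
    quiescent or UP branch terminates).
    """
    Ia_grid = np.asarray(Ia_grid, dtype=float)
    if Ia_grid.size and np.any(np.diff(Ia_grid) < 0):
        raise ValueError("Ia_grid must be ordered")
    quiescent, up, mid = [], [], []
    prev_up = prev_q = None
    for Ia in Ia_grid:
        guesses = [(0.0, 0.0), (0.3, 1.0), (1.0, 15.0), (3.0, 40.0)]
        for prev in (prev_up, prev_q):
            if prev is not None:
                guesses.append(prev)
        roots = []
        for g in guesses:
            pt = self_consistent_rates(params, Ia=Ia, init=g)
            if not pt.converged:
                continue
            if not any(abs(pt.r_E - q.r_E) < 1e-4 and abs(pt.r_I - q.r_I) < 1e-4 for q in roots):
                roots.append(pt)
        stable_roots = sorted((q for q in roots if q.stable), key=lambda q: q.r_E)
        unstable_roots = [q for q in roots if not q.stable]
        # two stable roots: lower = quiescent, upper = UP; a single stable
        # root is assigned by its position relative to the unstable middle
        # root, falling back to continuity with the existing branches
        if len(stable_roots) >= 2:
            quiescent.append(stable_roots[0])
            prev_q = (stable_roots[0].r_E, stable_roots[0].r_I)
            up.append(stable_roots[-1])
            prev_up = (stable_roots[-1].r_E, stable_roots[-1].r_I)
        elif len(stable_roots) == 1:
            s = stable_roots[0]
            if unstable_roots:
                is_up = s.r_E > unstable_roots[0].r_E
            elif prev_up is not None or prev_q is not None:
                d_up = abs(s.r_E - prev_up[0]) if prev_up else np.inf
                d_q = abs(s.r_E - prev_q[0]) if prev_q else np.inf
                is_up = d_up < d_q
            else:
                is_up = s.r_E >= 0.5
            if is_up:
                up.append(s)
                prev_up = (s.r_E, s.r_I)
            else:
                quiescent.append(s)
                prev_q = (s.r_E, s.r_I)
        if unstable_roots:
            mid.append(unstable_roots[0])

    branches = []
    for name, pts, stable in (("quiescent", quiescent, True), ("up", up, True),
                              ("unstable", mid, False)):
        if pts:
            branches.append(MeanFieldBranch(
                name=name,
                Ia=np.array([q.Ia for q in pts]),
                r_E=np.array([q.r_E for q in pts]),
                r_I=np.array([q.r_I for q in pts]),
                stable=stable,
            ))
    saddle_nodes = []
    bydict = {b.name: b for b in branches}
    if "up" in bydict and bydict["up"].Ia.size and bydict["up"].Ia[-1] < Ia_grid[-1]:
        saddle_nodes.append(float(bydict["up"].Ia[-1]))
    if "quiescent" in bydict and bydict["quiescent"].Ia.size and bydict["quiescent"].Ia[0] > Ia_grid[0]:
        saddle_nodes.append(float(bydict["quiescent"].Ia[0]))
    return {"branches": branches, "saddle_nodes": sorted(saddle_nodes)}
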