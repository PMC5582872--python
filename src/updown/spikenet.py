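"""All-to-all EI network of leaky integrate-and-fire neurons with AHP adaptation.

The membrane of neuron i in population X = {E, I} follows

    tau_X dV_i/dt = -(V_i - V_L) + I_rec^X(t) + I_ext,i(t) [- Ia_i(t) for E]

with reset to Vr_X on crossing theta_X (no refractory period). The external
input is independent Gaussian white noise per neuron plus brief synchronous
"kicks" delivered to a fixed 10% subpopulation; recurrent input passes
through population double-exponential synaptic filters with per-presynaptic-
neuron delays. Each E spike increments that neuron's after-hyperpolarization
current by beta_ahp / tau_a.

Because connectivity is all-to-all and delays are attached to the
presynaptic neuron, the recurrent drive collapses to delayed population
spike counts, which the jitted integration loop exploits. The white noise is
applied with the exact Ornstein-Uhlenbeck voltage discretization, so the
free-membrane voltage SD equals the configured sigma irrespective of dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PopulationSpikeData, StateIntervals
from ._spikenet_kernel import run_chunk
from . import udstats

__all__ = [
    "SpikingNetParams",
    "SpikingRecord",
    "simulate_spiking",
    "kick_train",
    "kick_response",
    "no_kick_variant",
    "population_rate_from_record",
    "isi_cv",
]


@dataclass(frozen=True)
class SpikingNetParams:
    """Parameters of the spiking EI network (voltages mV, times ms).

    The defaults are the kick-driven configuration: 4000 E and 1000 I
    neurons, EI asymmetry in threshold and membrane time constant, inhibitory
    synapses fast (1/1 ms rise/decay) and excitatory slow (8/23 ms), Poisson
    kicks at ~2.5 Hz hitting a fixed 10% of each population with
    state-dependent amplitude (halved during UP).
    """

    N_E: int = 4000
    N_I: int = 1000
    tau_E: float = 20.0
    tau_I: float = 10.0
    V_L: float = -57.4
    V_r_E: float = -51.0
    V_r_I: float = -49.9
    theta_spk_E: float = -45.0
    theta_spk_I: float = -43.9
    J_EE: float = 1.4
    J_EI: float = -0.35
    J_IE: float = 5.0
    J_II: float = -1.0
    tau_r_E: float = 8.0
    tau_d_E: float = 23.0
    tau_r_I: float = 1.0
    tau_d_I: float = 1.0
    tau_unit: float = 1.0
    delay_max_E: float = 1.0
    delay_max_I: float = 0.5
    sigma_white: float = 2.5  # free-membrane voltage SD (mV)
    kicks_enabled: bool = True
    kick_rate: float = 2.5
    kick_K_E_D: float = 220.0
    kick_K_E_U: float = 110.0
    kick_K_I_D: float = 88.0
    kick_K_I_U: float = 44.0
    kick_tau_k: float = 0.5
    kick_delta: float = 2.0
    kick_p: float = 0.1
    state_rate_window: float = 50.0   # trailing window (ms) for the online U/D proxy
    state_rate_threshold: float = 1.0  # Hz on the E population rate
    tau_a: float = 500.0
    beta_ahp: float = 300.0            # mV*ms; each spike adds beta_ahp/tau_a to Ia
    depol_E: float = 0.0
    depol_I: float = 0.0

    def __post_init__(self) -> None:
        if not (self.V_r_E < self.theta_spk_E and self.V_r_I < self.theta_spk_I):
            raise ValueError("reset potentials must lie below spike thresholds")
        for name in ("tau_E", "tau_I", "tau_r_E", "tau_d_E", "tau_r_I",
                     "tau_d_I", "tau_unit", "tau_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.kick_p <= 1.0:
            raise ValueError("kick target fraction must lie in [0, 1]")
        if self.kick_rate < 0:
            raise ValueError("kick rate must be non-negative")

    def with_(self, **kw) -> "SpikingNetParams":
        return replace(self, **kw)


def no_kick_variant(params: SpikingNetParams) -> SpikingNetParams:
    """Kick-free depolarized configuration.

    Kicks disabled; E cells depolarized by 5.6 mV (to sit just below
    threshold) and I cells by 6 mV; fast excitatory synapses (2/3 ms);
    weaker adaptation (200 mV*ms). Transitions are then driven by the
    independent noise alone.
    """
    return params.with_(
        kicks_enabled=False,
        depol_E=5.6,
        depol_I=6.0,
        tau_r_E=2.0,
        tau_d_E=3.0,
        beta_ahp=200.0,
    )


@dataclass
class SpikingRecord:
    """Output of a spiking-network simulation.

    ``spike_units``/``spike_times`` list every spike (unit ids < n_E are
    excitatory). Population traces are sampled every ``trace_dt`` seconds:
    synaptic variables s_E, s_I, the population-averaged AHP current Ia, and
    per-sample spike counts for each population. ``probe_v`` holds membrane
    traces for ``probe_ids``.
    """

    n_E: int
    n_I: int
    duration: float
    spike_units: np.ndarray
    spike_times: np.ndarray
    trace_time: np.ndarray
    s_E: np.ndarray
    s_I: np.ndarray
    Ia_mean: np.ndarray
    count_E: np.ndarray
    count_I: np.ndarray
    trace_dt: float
    probe_ids: np.ndarray
    probe_v: np.ndarray
    kick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    kick_K_E: np.ndarray = field(default_factory=lambda: np.empty(0))
    kick_K_I: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_population_data(self, population: str | None = None) -> PopulationSpikeData:
        """Repackage spikes as :class:`PopulationSpikeData`.

        ``population`` of ``"E"`` or ``"I"`` selects one subpopulation;
        ``None`` keeps all units.
        """
        if population == "E":
            ids = np.arange(self.n_E)
        elif population == "I":
            ids = np.arange(self.n_E, self.n_E + self.n_I)
        elif population is None:
            ids = np.arange(self.n_E + self.n_I)
        else:
            raise ValueError("population must be 'E', 'I' or None")
        order = np.argsort(self.spike_times, kind="stable")
        su = self.spike_units[order]
        st = self.spike_times[order]
        spikes = [st[su == i] for i in ids]
        labels = ["E" if i < self.n_E else "I" for i in ids]
        return PopulationSpikeData(spikes=spikes, duration=self.duration, unit_labels=labels)


def kick_train(rate: float, duration: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Homogeneous Poisson event times (seconds) on [0, duration)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def kick_response(
    params: SpikingNetParams,
    population: str = "E",
    K: float | None = None,
    dt: float = 0.01,
) -> float:
    """Peak depolarization of one isolated neuron receiving a single kick.

    Integrates ``tau_m dV/dt = -V + I_kick(t)`` from V = 0 (relative to
    rest) with the kick waveform ``K (1 - exp(-t/tau_k))`` on ``(0, Delta)``,
    without noise or recurrence, and returns the maximum of V in mV.
    """
    if population == "E":
        tau_m = params.tau_E
        if K is None:
            K = params.kick_K_E_D
    elif population == "I":
        tau_m = params.tau_I
        if K is None:
            K = params.kick_K_I_D
    else:
        raise ValueError("population must be 'E' or 'I'")
    t_end = params.kick_delta + 5.0 * tau_m
    n = int(round(t_end / dt))
    v = 0.0
    vmax = 0.0
    for k in range(n):
        t = k * dt

        def i_kick(tt):
            if 0.0 < tt <= params.kick_delta:
                return K * (1.0 - np.exp(-tt / params.kick_tau_k))
            return 0.0

        # RK2 (midpoint)
        k1 = (-v + i_kick(t)) / tau_m
        k2 = (-(v + 0.5 * dt * k1) + i_kick(t + 0.5 * dt)) / tau_m
        v = v + dt * k2
        vmax = max(vmax, v)
    return float(vmax)


def simulate_spiking(
    params: SpikingNetParams,
    duration: float,
    dt: float = 0.05,
    seed: int | np.random.Generator = 0,
    probe_ids=(),
    trace_dt: float = 0.001,
    chunk_steps: int = 2000,
) -> SpikingRecord:
    """Simulate the network for ``duration`` seconds with step ``dt`` ms.

    Noise is generated in chunks with numpy and the integration loop is
    numba-jitted. The kick target subsets, delays and kick train are drawn
    once from ``seed`` at construction; the same seed reproduces the run
    exactly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    NE, NI = params.N_E, params.N_I
    N = NE + NI
    n_steps = int(round(duration * 1000.0 / dt))
    dt_s = dt / 1000.0

    # construction-time randomness: delays, kick targets, kick train
    delay_E = rng.uniform(0.0, params.delay_max_E, NE)
    delay_I = rng.uniform(0.0, params.delay_max_I, NI)
    delay_steps = np.concatenate(
        [np.round(delay_E / dt).astype(np.int64), np.round(delay_I / dt).astype(np.int64)]
    )
    targeted = np.zeros(N, dtype=np.bool_)
    n_tE = int(round(params.kick_p * NE))
    n_tI = int(round(params.kick_p * NI))
    targeted[rng.choice(NE, n_tE, replace=False)] = True
    targeted[NE + rng.choice(NI, n_tI, replace=False)] = True

    if params.kicks_enabled and params.kick_rate > 0:
        kick_times = kick_train(params.kick_rate, duration, rng)
    else:
        kick_times = np.empty(0)
    kick_steps = np.floor(kick_times / dt_s).astype(np.int64)
    kick_K_E = np.zeros(kick_steps.size)
    kick_K_I = np.zeros(kick_steps.size)

    # precomputed propagation constants
    dec_E = np.exp(-dt / params.tau_E)
    dec_I = np.exp(-dt / params.tau_I)
    noise_E = params.sigma_white * np.sqrt(1.0 - dec_E**2)
    noise_I = params.sigma_white * np.sqrt(1.0 - dec_I**2)
    dec_a = np.exp(-dt / params.tau_a)
    ahp_inc = params.beta_ahp / params.tau_a

    def syn_coefs(tau_r, tau_d):
        er = np.exp(-dt / tau_r)
        ed = np.exp(-dt / tau_d)
        if abs(tau_r - tau_d) < 1e-12:
            c = (dt / tau_d) * ed
        else:
            c = tau_r / (tau_r - tau_d) * (er - ed)
        return er, ed, c

    er_E, ed_E, c_E = syn_coefs(params.tau_r_E, params.tau_d_E)
    er_I, ed_I, c_I = syn_coefs(params.tau_r_I, params.tau_d_I)
    imp_E = params.tau_unit / params.tau_r_E
    imp_I = params.tau_unit / params.tau_r_I

    buf_len = int(np.max(delay_steps)) + 2 if N else 2
    trace_stride = max(int(round(trace_dt * 1000.0 / dt)), 1)
    # keep chunk boundaries aligned with trace samples
    chunk_steps = max(chunk_steps // trace_stride, 1) * trace_stride
    n_trace = n_steps // trace_stride
    win_steps = max(int(round(params.state_rate_window / dt)), 1)

    probe_ids = np.asarray(list(probe_ids), dtype=np.int64)

    # persistent state
    V = np.full(N, params.V_L)
    Ia = np.zeros(NE)
    buf_E = np.zeros(buf_len)
    buf_I = np.zeros(buf_len)
    win_buf = np.zeros(win_steps)
    scal = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    # scal: [u_E, s_E, u_I, s_I, Ia_sum, win_sum]

    tr_sE = np.empty(n_trace)
    tr_sI = np.empty(n_trace)
    tr_Ia = np.empty(n_trace)
    tr_cE = np.zeros(n_trace)
    tr_cI = np.zeros(n_trace)
    probe_v = np.empty((probe_ids.size, n_trace))

    all_units: list[np.ndarray] = []
    all_steps: list[np.ndarray] = []
    cap = max(int(chunk_steps * dt_s * N * 40.0), 20000)

    dur_steps = int(round(params.kick_delta / dt))
    rate_norm = 1.0 / (NE * win_steps * dt_s)  # win_sum -> Hz per E neuron

    step0 = 0
    while step0 < n_steps:
        S = min(chunk_steps, n_steps - step0)
        noise = rng.standard_normal((S, N), dtype=np.float32)
        while True:
            snap = (V.copy(), Ia.copy(), buf_E.copy(), buf_I.copy(),
                    win_buf.copy(), scal.copy())
            sp_units = np.empty(cap, dtype=np.int64)
            sp_steps = np.empty(cap, dtype=np.int64)
            n_spk = run_chunk(
                step0, S, dt, V, Ia, buf_E, buf_I, win_buf, scal, noise,
                delay_steps, targeted, NE, NI,
                params.V_L + params.depol_E, params.V_L + params.depol_I,
                params.V_r_E, params.V_r_I,
                params.theta_spk_E, params.theta_spk_I,
                dec_E, dec_I, noise_E, noise_I, dec_a, ahp_inc,
                er_E, ed_E, c_E, er_I, ed_I, c_I, imp_E, imp_I,
                params.J_EE, params.J_EI, params.J_IE, params.J_II,
                kick_steps, kick_K_E, kick_K_I,
                params.kick_K_E_D, params.kick_K_E_U,
                params.kick_K_I_D, params.kick_K_I_U,
                params.kick_tau_k, dur_steps,
                rate_norm, params.state_rate_threshold,
                trace_stride, tr_sE, tr_sI, tr_Ia, tr_cE, tr_cI,
                probe_ids, probe_v,
                sp_units, sp_steps,
            )
            if n_spk >= 0:
                break
            # spike buffer overflow: restore state and retry with larger cap
            V, Ia, buf_E, buf_I, win_buf, scal = snap
            cap *= 2
            if cap > 8_000_000:
                raise FloatingPointError(
                    f"runaway spiking near t={step0 * dt_s:.3f} s: "
                    "spike rate exceeds any physiological bound"
                )
        if n_spk == -2:
            raise FloatingPointError(f"numeric overflow near step {step0}")
        all_units.append(sp_units[:n_spk].copy())
        all_steps.append(sp_steps[:n_spk].copy())
        step0 += S

    units = np.concatenate(all_units) if all_units else np.empty(0, dtype=np.int64)
    steps = np.concatenate(all_steps) if all_steps else np.empty(0, dtype=np.int64)
    return SpikingRecord(
        n_E=NE,
        n_I=NI,
        duration=duration,
        spike_units=units,
        spike_times=steps * dt_s,
        trace_time=(np.arange(n_trace) + 1) * trace_stride * dt_s,
        s_E=tr_sE,
        s_I=tr_sI,
        Ia_mean=tr_Ia,
        count_E=tr_cE,
        count_I=tr_cI,
        trace_dt=trace_stride * dt_s,
        probe_ids=probe_ids,
        probe_v=probe_v,
        kick_times=kick_times,
        kick_K_E=kick_K_E,
        kick_K_I=kick_K_I,
    )


def population_rate_from_record(
    record: SpikingRecord, population: str = "E", kernel_T: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Square-kernel population rate trace (Hz) for one population."""
    data = record.to_population_data(population)
    return udstats.population_rate(data, kernel_T=kernel_T)


def isi_cv(
    record: SpikingRecord,
    intervals: StateIntervals,
    population: str = "E",
    min_isis: int = 5,
) -> float:
    """Mean per-neuron CV of inter-spike intervals within UP periods.

    ISIs are counted only when both spikes of a pair fall inside the same U
    period; they are pooled per neuron, the CV is computed per neuron with at
    least ``min_isis`` intervals, and averaged across qualifying neurons.
    Returns NaN if no neuron qualifies.
    """
    data = record.to_population_data(population)
    u_mask = np.array([s == "U" for s in intervals.states])
    u_on = intervals.onsets[u_mask]
    u_off = intervals.offsets[u_mask]
    cvs = []
    for s in data.spikes:
        if len(s) < 2:
            continue
        isis = []
        for a, b in zip(u_on, u_off):
            inside = s[(s >= a) & (s < b)]
            if len(inside) >= 2:
                isis.append(np.diff(inside))
        if not isis:
            continue
        pooled = np.concatenate(isis)
        if len(pooled) >= min_isis and np.mean(pooled) > 0:
            cvs.append(np.std(pooled) / np.mean(pooled))
    return float(np.mean(cvs)) if cvs else float("nan")
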