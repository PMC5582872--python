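"""Synthetic population spike trains with known UP/DOWN ground truth.

Emulates extracellular population recordings during a synchronized brain
state: a two-state alternating renewal process with gamma-distributed U/D
durations (CV ~ 0.7), state-dependent inhomogeneous Poisson firing across
heterogeneous units (lognormal UP rates around 3.7 spikes/s, sparse DOWN
firing around 0.018 spikes/s), optional within-state linear rate ramps,
optional slow sinusoidal drift of the mean durations, and optional
adjacent-period coupling through a latent adaptation level that builds up
during U and recovers during D — short U periods leave little adaptation,
shortening the next D, which yields positive duration correlations at lags
0 and 1 only.

What it does not emulate: spike waveforms, LFP, cell-type structure, or
refractoriness; firing is conditionally Poisson given the state sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import PopulationSpikeData, StateIntervals

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_population",
    "gen_from_model",
    "CALIBRATED_COUPLING",
]

#: Latent-adaptation gain for which the corrected serial correlation of the
#: generated sequences is ~0.2 at lag 0 (the magnitude reported for cortical
#: recordings), with lag-1 slightly lower and higher lags null.
CALIBRATED_COUPLING = 1.2


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration (durations s, rates Hz)."""

    n_units: int = 64
    duration: float = 300.0
    gamma_shape_U: float = 2.0
    gamma_scale_U: float = 0.25
    gamma_shape_D: float = 2.0
    gamma_scale_D: float = 0.25
    coupling: float = 0.0        # latent-adaptation gain; CALIBRATED_COUPLING gives Corr ~ 0.2 at lag 0
    coupling_tau: float = 0.5    # latent relaxation time (s)
    drift_amplitude: float = 0.0  # fractional modulation of mean durations
    drift_period: float = 300.0   # s
    up_rate_mean: float = 3.7     # mean of the lognormal per-unit UP rates
    up_rate_sigma: float = 0.5    # sigma of log rate
    down_rate: float = 0.018
    ramp_U: float | np.ndarray = 0.0  # fractional rate change over a U period
    ramp_D: float | np.ndarray = 0.0  # same for D periods
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gamma_shape_U", "gamma_scale_U", "gamma_shape_D", "gamma_scale_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.up_rate_mean < 0 or self.down_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """True state sequence and per-unit rate parameters of a generated set."""

    intervals: StateIntervals
    up_rates: np.ndarray
    down_rate: float
    ramp_U: np.ndarray
    ramp_D: np.ndarray
    latent: np.ndarray = field(default_factory=lambda: np.empty(0))


def _draw_state_sequence(cfg: SynthConfig, rng) -> tuple[StateIntervals, np.ndarray]:
    """Alternating renewal sequence starting in D at t = 0."""
    states, onsets, offsets, latents = [], [], [], []
    t = 0.0
    a = 0.0  # latent adaptation in [0, 1]
    state = "D"
    while t < cfg.duration:
        if state == "D":
            shape, scale = cfg.gamma_shape_D, cfg.gamma_scale_D
            mult = np.exp(cfg.coupling * (a - 0.5)) if cfg.coupling else 1.0
        else:
            shape, scale = cfg.gamma_shape_U, cfg.gamma_scale_U
            mult = np.exp(cfg.coupling * (0.5 - a)) if cfg.coupling else 1.0
        if cfg.drift_amplitude:
            mult *= 1.0 + cfg.drift_amplitude * np.sin(2 * np.pi * t / cfg.drift_period)
        dur = rng.gamma(shape, scale * max(mult, 1e-3))
        dur = max(dur, 1e-4)
        end = min(t + dur, cfg.duration)
        states.append(state)
        onsets.append(t)
        offsets.append(end)
        latents.append(a)
        # latent relaxation over the realized period
        if state == "U":
            a = 1.0 + (a - 1.0) * np.exp(-(end - t) / cfg.coupling_tau)
        else:
            a = a * np.exp(-(end - t) / cfg.coupling_tau)
        t = end
        state = "U" if state == "D" else "D"
    return (
        StateIntervals(states=states, onsets=np.array(onsets), offsets=np.array(offsets)),
        np.array(latents),
    )


def _ramped_times(rng, n: int, f: float) -> np.ndarray:
    """Positions in [0, 1] with linear density 1 + f (x - 1/2) (|f| <= 2)."""
    u = rng.uniform(0.0, 1.0, n)
    if abs(f) < 1e-12:
        return u
    # CDF(x) = x + f/2 x^2 - f/2 x -> solve (f/2) x^2 + (1 - f/2) x - u = 0
    aa = f / 2.0
    bb = 1.0 - f / 2.0
    disc = bb * bb + 4.0 * aa * u
    return (-bb + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * aa)


def gen_population(cfg: SynthConfig) -> tuple[PopulationSpikeData, GroundTruth]:
    """Generate a spike-train population with known ground truth."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.duration == 0 or cfg.n_units == 0:
        truth = GroundTruth(
            intervals=StateIntervals(states=["D"], onsets=np.array([0.0]),
                                     offsets=np.array([max(cfg.duration, 1e-9)])),
            up_rates=np.empty(0), down_rate=cfg.down_rate,
            ramp_U=np.empty(0), ramp_D=np.empty(0),
        )
        return PopulationSpikeData(spikes=[], duration=cfg.duration), truth

    intervals, latent = _draw_state_sequence(cfg, rng)

    mu_log = np.log(cfg.up_rate_mean) - 0.5 * cfg.up_rate_sigma**2
    up_rates = rng.lognormal(mu_log, cfg.up_rate_sigma, cfg.n_units)
    ramp_U = np.broadcast_to(np.asarray(cfg.ramp_U, dtype=float), (cfg.n_units,)).copy()
    ramp_D = np.broadcast_to(np.asarray(cfg.ramp_D, dtype=float), (cfg.n_units,)).copy()

    spikes: list[list[np.ndarray]] = [[] for _ in range(cfg.n_units)]
    for j in range(len(intervals)):
        t0, t1 = intervals.onsets[j], intervals.offsets[j]
        dur = t1 - t0
        is_up = intervals.states[j] == "U"
        for u in range(cfg.n_units):
            rate = up_rates[u] if is_up else cfg.down_rate
            if rate <= 0:
                continue
            n = rng.poisson(rate * dur)
            if n == 0:
                continue
            f = ramp_U[u] if is_up else ramp_D[u]
            x = _ramped_times(rng, n, f)
            spikes[u].append(t0 + np.sort(x) * dur)
    arrays = [
        np.concatenate(s) if s else np.empty(0) for s in spikes
    ]
    data = PopulationSpikeData(spikes=arrays, duration=cfg.duration)
    truth = GroundTruth(
        intervals=intervals, up_rates=up_rates, down_rate=cfg.down_rate,
        ramp_U=ramp_U, ramp_D=ramp_D, latent=latent,
    )
    return data, truth


def gen_from_model(
    source: str,
    params,
    duration: float,
    seed: int = 0,
    n_units: int = 64,
    rate_scale_sigma: float = 0.5,
) -> PopulationSpikeData:
    """Bridge the simulators to the analysis pipeline.

    ``source="ratenet"`` thins inhomogeneous Poisson unit spikes from the
    simulated r_E(t), each unit scaled by a lognormal factor (unit mean 1);
    ``source="spikenet"`` repackages simulated network spikes directly,
    subsampling ``n_units`` random units.
    """
    if duration == 0:
        return PopulationSpikeData(spikes=[], duration=0.0)
    rng = np.random.default_rng(seed)
    if source == "ratenet":
        from .ratenet import simulate_rate

        traj = simulate_rate(params, duration, seed=rng.integers(2**31))
        dt_s = traj.dt_ms / 1000.0
        scales = rng.lognormal(-0.5 * rate_scale_sigma**2, rate_scale_sigma, n_units)
        spikes = []
        expected = traj.r_E * dt_s
        for u in range(n_units):
            counts = rng.poisson(expected * scales[u])
            idx = np.flatnonzero(counts)
            times = np.repeat(traj.time[idx], counts[idx]) + rng.uniform(0, dt_s, counts.sum())
            spikes.append(np.sort(times))
        return PopulationSpikeData(spikes=spikes, duration=duration)
    if source == "spikenet":
        from .spikenet import simulate_spiking

        record = simulate_spiking(params, duration, seed=rng.integers(2**31))
        data = record.to_population_data()
        ids = np.sort(rng.choice(data.n_units, size=min(n_units, data.n_units), replace=False))
        return data.subset(ids)
    raise ValueError("source must be 'ratenet' or 'spikenet'")
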