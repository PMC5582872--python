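"""Spiking network: kicks, synapses, AHP, and the population-sum collapse."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import simpson

from updown.spikenet import (
    SpikingNetParams,
    kick_response,
    kick_train,
    no_kick_variant,
    simulate_spiking,
)


class TestKickTrain:
    def test_zero_rate_empty(self):
        assert kick_train(0.0, 100.0).size == 0

    def test_poisson_count(self):
        times = kick_train(2.5, 1000.0, seed=0)
        assert abs(times.size - 2500) <= 100  # mean +- 2 SD

    def test_exponential_intervals(self):
        times = kick_train(10.0, 1100.0, seed=1)[:10_001]
        isis = np.diff(times)
        stat = sps.kstest(isis, "expon", args=(0, isis.mean()))
        assert stat.pvalue > 0.01

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            kick_train(-1.0, 10.0)


class TestKickResponse:
    def test_e_cell_peak_depolarization(self):
        p = SpikingNetParams()
        assert kick_response(p, "E") == pytest.approx(16.1, rel=0.02)

    def test_i_cell_peak_depolarization(self):
        p = SpikingNetParams()
        assert kick_response(p, "I") == pytest.approx(12.4, rel=0.02)

    def test_zero_amplitude(self):
        assert kick_response(SpikingNetParams(), "E", K=0.0) == 0.0


def _syn_response(tau_r, tau_d, dt=0.01, tau_unit=1.0, horizon=60.0):
    """Sample the double-exponential filter response to one spike using the
    same exact propagator as the simulator."""
    er = np.exp(-dt / tau_r)
    ed = np.exp(-dt / tau_d)
    if abs(tau_r - tau_d) < 1e-12:
        c = (dt / tau_d) * ed
    else:
        c = tau_r / (tau_r - tau_d) * (er - ed)
    n = int(horizon * max(tau_r, tau_d) / dt)
    s_series = np.empty(n + 1)
    u, s = tau_unit / tau_r, 0.0
    s_series[0] = 0.0
    for k in range(n):
        s = s * ed + u * c
        u *= er
        s_series[k + 1] = s
    return s_series, dt


class TestSynapticFilter:
    @pytest.mark.parametrize("tau_r, tau_d", [(8.0, 23.0), (1.0, 1.0), (2.0, 3.0)])
    def test_unitary_event_area_is_tau_unit(self, tau_r, tau_d):
        s, dt = _syn_response(tau_r, tau_d)
        area = simpson(s, dx=dt)
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_steady_state_tracks_input_rate(self):
        # constant presynaptic drive nu_tot -> s = tau_unit * nu_tot
        dt = 0.05
        er = np.exp(-dt / 8.0)
        ed = np.exp(-dt / 23.0)
        c = 8.0 / (8.0 - 23.0) * (er - ed)
        u = s = 0.0
        arrivals = 3.0  # per step -> 60 per ms
        for _ in range(40_000):
            u += arrivals / 8.0  # tau_unit / tau_r per spike
            s = s * ed + u * c
            u *= er
        assert s == pytest.approx(60.0, rel=0.01)


def _small_params(**kw):
    base = dict(
        N_E=16, N_I=4, sigma_white=2.5, kick_rate=20.0,
        kick_p=0.25, J_EE=0.5, J_EI=-0.3, J_IE=0.8, J_II=-0.4,
    )
    base.update(kw)
    return SpikingNetParams(**base)


class TestSimulateSpiking:
    def test_silent_without_drive(self):
        p = _small_params(sigma_white=0.0, kicks_enabled=False)
        rec = simulate_spiking(p, 0.5, seed=0)
        assert rec.spike_times.size == 0

    def test_ahp_increment_and_decay(self):
        # one isolated depolarized E neuron: each spike adds beta/tau_a to Ia
        p = SpikingNetParams(
            N_E=1, N_I=1, sigma_white=0.0, kicks_enabled=False,
            J_EE=0.0, J_EI=0.0, J_IE=0.0, J_II=0.0, depol_E=13.5,
        )
        rec = simulate_spiking(p, 2.0, seed=0)
        e_spikes = rec.spike_times[rec.spike_units == 0]
        assert e_spikes.size >= 3
        i0 = int(e_spikes[0] / rec.trace_dt)
        jump = rec.Ia_mean[i0 + 1] - rec.Ia_mean[max(i0 - 1, 0)]
        assert jump == pytest.approx(0.6, abs=0.02)
        # decay between first and second spike follows tau_a = 500 ms
        i1 = int(e_spikes[1] / rec.trace_dt)
        if i1 - i0 > 10:
            expected = rec.Ia_mean[i0 + 1] * np.exp(-(i1 - 1 - (i0 + 1)) * rec.trace_dt * 1000 / 500.0)
            assert rec.Ia_mean[i1 - 1] == pytest.approx(expected, rel=0.02)

    def test_spike_times_strictly_increasing_per_neuron(self):
        rec = simulate_spiking(_small_params(), 2.0, seed=3)
        data = rec.to_population_data()
        for s in data.spikes:
            if s.size > 1:
                assert np.all(np.diff(s) > 0)

    def test_probe_voltage_below_threshold(self):
        p = _small_params()
        rec = simulate_spiking(p, 1.0, seed=4, probe_ids=[0])
        # recorded samples never exceed threshold except at reset instants
        assert rec.probe_v.max() <= p.theta_spk_E + 1e-9

    def test_reproducible_and_seed_sensitive(self):
        p = _small_params()
        a = simulate_spiking(p, 0.5, seed=5)
        b = simulate_spiking(p, 0.5, seed=5)
        c = simulate_spiking(p, 0.5, seed=6)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert not np.array_equal(a.spike_times, c.spike_times)

    def test_dt_cap_enforced(self):
        with pytest.raises(ValueError):
            simulate_spiking(_small_params(), 0.1, dt=0.1)


class TestPopulationSumCollapse:
    def test_per_neuron_oracle_agrees(self):
        """All-to-all recurrence via delayed population sums matches an
        explicit per-presynaptic-neuron synaptic-filter computation."""
        p = _small_params()
        rec = simulate_spiking(p, 1.0, seed=7, probe_ids=[0, 17])
        oracle = _per_neuron_oracle(p, 1.0, seed=7, probe_ids=[0, 17])
        assert np.array_equal(rec.spike_units, oracle["units"])
        assert np.array_equal(rec.spike_times, oracle["times"])
        assert np.allclose(rec.probe_v, oracle["probe_v"], atol=1e-8)


def _per_neuron_oracle(params, duration, seed, probe_ids):
    """Python reimplementation holding one synaptic filter per presynaptic
    neuron; recurrent input is the explicit sum over presynaptic filters."""
    rng = np.random.default_rng(seed)
    NE, NI = params.N_E, params.N_I
    N = NE + NI
    dt = 0.05
    dt_s = dt / 1000.0
    n_steps = int(round(duration * 1000.0 / dt))

    delay_E = rng.uniform(0.0, params.delay_max_E, NE)
    delay_I = rng.uniform(0.0, params.delay_max_I, NI)
    delay_steps = np.concatenate(
        [np.round(delay_E / dt).astype(np.int64), np.round(delay_I / dt).astype(np.int64)]
    )
    targeted = np.zeros(N, dtype=bool)
    targeted[rng.choice(NE, int(round(params.kick_p * NE)), replace=False)] = True
    targeted[NE + rng.choice(NI, int(round(params.kick_p * NI)), replace=False)] = True
    if params.kicks_enabled and params.kick_rate > 0:
        n_k = rng.poisson(params.kick_rate * duration)
        kick_times = np.sort(rng.uniform(0.0, duration, n_k))
    else:
        kick_times = np.empty(0)
    kick_steps = np.floor(kick_times / dt_s).astype(np.int64)
    kick_K_E = np.zeros(kick_steps.size)
    kick_K_I = np.zeros(kick_steps.size)

    dec = np.where(np.arange(N) < NE, np.exp(-dt / params.tau_E), np.exp(-dt / params.tau_I))
    namp = np.where(
        np.arange(N) < NE,
        params.sigma_white * np.sqrt(1 - np.exp(-2 * dt / params.tau_E)),
        params.sigma_white * np.sqrt(1 - np.exp(-2 * dt / params.tau_I)),
    )

    def coefs(tr, td):
        er, ed = np.exp(-dt / tr), np.exp(-dt / td)
        c = (dt / td) * ed if abs(tr - td) < 1e-12 else tr / (tr - td) * (er - ed)
        return er, ed, c

    er_E, ed_E, c_E = coefs(params.tau_r_E, params.tau_d_E)
    er_I, ed_I, c_I = coefs(params.tau_r_I, params.tau_d_I)
    imp_E = params.tau_unit / params.tau_r_E
    imp_I = params.tau_unit / params.tau_r_I
    dec_a = np.exp(-dt / params.tau_a)
    ahp_inc = params.beta_ahp / params.tau_a

    # one (u, s) pair per presynaptic neuron
    u = np.zeros(N)
    s = np.zeros(N)
    buf_len = int(delay_steps.max()) + 2
    buf = np.zeros((buf_len, N))
    V = np.full(N, params.V_L)
    Ia = np.zeros(NE)
    win_steps = int(round(params.state_rate_window / dt))
    win = np.zeros(win_steps)
    win_sum = 0.0
    rate_norm = 1.0 / (NE * win_steps * dt_s)

    trace_stride = 20
    n_trace = n_steps // trace_stride
    probe_v = np.empty((len(probe_ids), n_trace))
    units, steps_out = [], []
    chunk = max(2000 // trace_stride, 1) * trace_stride
    noise = None
    dur_steps = int(round(params.kick_delta / dt))
    resolve = 0

    for g in range(n_steps):
        if g % chunk == 0:
            S = min(chunk, n_steps - g)
            noise = rng.standard_normal((S, N), dtype=np.float32)
        slot = g % buf_len
        arr = buf[slot].copy()
        buf[slot] = 0.0
        u[:NE] += imp_E * arr[:NE]
        u[NE:] += imp_I * arr[NE:]
        s[:NE] = s[:NE] * ed_E + u[:NE] * c_E
        u[:NE] *= er_E
        s[NE:] = s[NE:] * ed_I + u[NE:] * c_I
        u[NE:] *= er_I
        sE = s[:NE].sum()
        sI = s[NE:].sum()
        while resolve < kick_steps.size and kick_steps[resolve] <= g:
            up = win_sum * rate_norm >= params.state_rate_threshold
            kick_K_E[resolve] = params.kick_K_E_U if up else params.kick_K_E_D
            kick_K_I[resolve] = params.kick_K_I_U if up else params.kick_K_I_D
            resolve += 1
        IkE = IkI = 0.0
        for k in range(kick_steps.size):
            rel = g - kick_steps[k]
            if 0 < rel <= dur_steps:
                w = 1.0 - np.exp(-rel * dt / params.kick_tau_k)
                IkE += kick_K_E[k] * w
                IkI += kick_K_I[k] * w
        base = np.where(
            np.arange(N) < NE,
            params.V_L + params.depol_E + params.J_EE * sE + params.J_EI * sI,
            params.V_L + params.depol_I + params.J_IE * sE + params.J_II * sI,
        )
        Ia *= dec_a
        base[:NE] -= Ia
        base[:NE][targeted[:NE]] += IkE
        base[NE:][targeted[NE:]] += IkI
        V = base + (V - base) * dec + namp * noise[g % chunk].astype(np.float64)
        th = np.where(np.arange(N) < NE, params.theta_spk_E, params.theta_spk_I)
        fired = V >= th
        cnt_E = float(fired[:NE].sum())
        for i in np.flatnonzero(fired):
            units.append(i)
            steps_out.append(g)
            V[i] = params.V_r_E if i < NE else params.V_r_I
            if i < NE:
                Ia[i] += ahp_inc
            buf[(g + delay_steps[i] + 1) % buf_len, i] += 1.0
        wslot = g % win_steps
        win_sum += cnt_E - win[wslot]
        win[wslot] = cnt_E
        if (g + 1) % trace_stride == 0:
            ti = (g + 1) // trace_stride - 1
            for pi, pid in enumerate(probe_ids):
                probe_v[pi, ti] = V[pid]
    return {
        "units": np.array(units, dtype=np.int64),
        "times": np.array(steps_out, dtype=np.int64) * dt_s,
        "probe_v": probe_v,
    }


class TestNoKickVariant:
    def test_configuration(self):
        p = no_kick_variant(SpikingNetParams())
        assert not p.kicks_enabled
        assert p.depol_E == 5.6 and p.depol_I == 6.0
        assert (p.tau_r_E, p.tau_d_E) == (2.0, 3.0)
        assert p.beta_ahp == 200.0

    def test_toggle_restores_defaults(self):
        p = no_kick_variant(SpikingNetParams())
        back = p.with_(kicks_enabled=True, depol_E=0.0, depol_I=0.0,
                       tau_r_E=8.0, tau_d_E=23.0, beta_ahp=300.0)
        assert back == SpikingNetParams()


class TestParamValidation:
    def test_reset_must_be_subthreshold(self):
        with pytest.raises(ValueError):
            SpikingNetParams(V_r_E=-40.0)

    def test_kick_fraction_bounds(self):
        with pytest.raises(ValueError):
            SpikingNetParams(kick_p=1.5)
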