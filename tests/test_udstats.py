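"""Interval statistics: durations, CV/CV2, gamma fits, correlograms, rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from updown.core import PopulationSpikeData, StateIntervals
from updown.udstats import (
    DurationSequences,
    aligned_rate,
    autocorrelogram,
    cv2_local,
    duration_stats,
    durations,
    gamma_fit,
    onset_offset_analysis,
    population_rate,
    serial_correlation,
    silence_density_epochs,
)


class TestDurations:
    def test_pairing_convention(self, simple_intervals):
        seqs = durations(simple_intervals)
        assert np.allclose(seqs.U, [0.5, 0.8])
        assert np.allclose(seqs.D, [1.0, 0.7])
        assert np.allclose(seqs.u_onsets, [1.0, 2.2])

    def test_single_interval_rejected(self):
        iv = StateIntervals(states=["U"], onsets=np.array([0.0]), offsets=np.array([1.0]))
        with pytest.raises(ValueError):
            durations(iv)

    def test_duration_conservation(self, simple_intervals):
        seqs = durations(simple_intervals)
        assert seqs.U.sum() + seqs.D.sum() == pytest.approx(
            simple_intervals.total_duration
        )


class TestDurationStats:
    def test_constant_sequence(self):
        s = duration_stats([2.0, 2.0, 2.0])
        assert s.cv == 0 and s.cv2 == 0 and s.mean == 2.0

    def test_cv2_closed_form(self):
        assert cv2_local([1.0, 3.0]) == pytest.approx(1.0)

    def test_exponential_cv_is_one(self):
        rng = np.random.default_rng(3)
        s = duration_stats(rng.exponential(2.0, 10**5))
        assert s.cv == pytest.approx(1.0, abs=0.01)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0.01, 100.0), min_size=2, max_size=50),
           st.floats(0.1, 10.0))
    def test_cv2_bounded_and_scale_invariant(self, xs, scale):
        x = np.array(xs)
        v = cv2_local(x)
        assert 0 <= v <= 2.0
        assert cv2_local(scale * x) == pytest.approx(v, rel=1e-9)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            duration_stats([0.0, 0.0])


class TestGammaFit:
    def test_self_recovery(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(1.1, 0.7, 5000)
        shape, scale = gamma_fit(x)
        assert shape == pytest.approx(1.1, abs=0.05)
        assert shape * scale == pytest.approx(x.mean(), rel=1e-6)

    def test_exponential_gives_shape_one(self):
        rng = np.random.default_rng(2)
        shape, _ = gamma_fit(rng.exponential(0.5, 5000))
        assert shape == pytest.approx(1.0, abs=0.05)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            gamma_fit([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            gamma_fit([1.0, -2.0])

    @pytest.mark.parametrize("shape", [0.5, 1.0, 2.0, 3.0])
    def test_bias_small_at_n300(self, shape):
        # desk-scale regime: shape recovered within +-15% on n=300 samples
        rng = np.random.default_rng(int(shape * 10))
        est = np.mean([gamma_fit(rng.gamma(shape, 0.5, 300))[0] for _ in range(20)])
        assert est == pytest.approx(shape, rel=0.15)


def _null_seqs(rng, M=200, mean_u=0.5, mean_d=0.45):
    U = rng.gamma(2.0, mean_u / 2.0, M)
    D = rng.gamma(2.0, mean_d / 2.0, M)
    onsets = np.cumsum(U + D)
    return DurationSequences(U=U, D=D, u_onsets=onsets)


class TestSerialCorrelation:
    def test_null_sequences_inside_global_band(self):
        rng = np.random.default_rng(0)
        violations = 0
        for _ in range(20):
            sc = serial_correlation(_null_seqs(rng), L_cov=100, L_band=400, seed=rng)
            if np.any((sc.corr < sc.global_band[0]) | (sc.corr > sc.global_band[1])):
                violations += 1
        assert violations <= 3  # ~5% expected under the null

    def test_global_band_calibration(self):
        # false-positive rate of the global band across null realizations ~ 5%
        rng = np.random.default_rng(42)
        viol = 0
        n_real = 100
        for _ in range(n_real):
            sc = serial_correlation(_null_seqs(rng, M=120), L_cov=100, L_band=1000,
                                    seed=rng)
            if np.any((sc.corr < sc.global_band[0]) | (sc.corr > sc.global_band[1])):
                viol += 1
        assert viol / n_real < 0.12  # 5% nominal, binomial slack at n=100

    def test_drift_induced_correlation_removed(self):
        # common slow modulation inflates the raw correlation at many lags but
        # the within-window shuffle correction nulls it
        rng = np.random.default_rng(7)
        M = 400
        t = np.cumsum(rng.gamma(2.0, 0.5, M))
        mod = 1.0 + 0.8 * np.sin(2 * np.pi * t / 300.0)
        U = rng.gamma(2.0, 0.25, M) * mod
        D = rng.gamma(2.0, 0.25, M) * mod
        seqs = DurationSequences(U=U, D=D, u_onsets=t)
        sc = serial_correlation(seqs, L_cov=200, L_band=500, seed=1)
        assert np.max(np.abs(sc.raw_corr)) > 0.15
        inside = (sc.corr >= sc.global_band[0]) & (sc.corr <= sc.global_band[1])
        assert inside.mean() > 0.9

    def test_outliers_excluded(self):
        rng = np.random.default_rng(5)
        seqs = _null_seqs(rng, M=100)
        seqs.U[50] = 100.0  # gross outlier
        sc = serial_correlation(seqs, L_cov=50, L_band=100, seed=2)
        assert np.all(np.abs(sc.corr) < 1.0)

    def test_too_few_periods_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            serial_correlation(_null_seqs(rng, M=5))


class TestPopulationRate:
    def test_square_kernel_arithmetic(self):
        # 10 units, one spike each at t=0.5 s, T=100 ms -> 10 Hz in the window
        data = PopulationSpikeData(spikes=[np.array([0.5])] * 10, duration=1.0)
        t, R = population_rate(data, kernel_T=100.0)
        assert R.max() == pytest.approx(10.0)
        assert R[t < 0.4].max() == 0.0

    def test_normalization_independent_of_n(self):
        rng = np.random.default_rng(0)
        mk = lambda n: PopulationSpikeData(
            spikes=[np.sort(rng.uniform(0, 100, 300)) for _ in range(n)], duration=100.0
        )
        _, R1 = population_rate(mk(10))
        _, R2 = population_rate(mk(20))
        assert R1.mean() == pytest.approx(R2.mean(), rel=0.05)

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        data = PopulationSpikeData(
            spikes=[np.sort(rng.uniform(1, 9, 50)) for _ in range(4)], duration=10.0
        )
        t, R = population_rate(data, kernel_T=100.0)
        total = R.sum() * 0.001 * data.n_units
        assert total == pytest.approx(data.n_spikes, rel=0.01)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            population_rate(PopulationSpikeData(spikes=[], duration=1.0))


def _blocky_intervals(rng, duration=200.0):
    states, onsets, offsets = [], [], []
    t, s = 0.0, "D"
    while t < duration:
        d = rng.gamma(2.0, 0.35)
        states.append(s)
        onsets.append(t)
        offsets.append(min(t + d, duration))
        t += d
        s = "U" if s == "D" else "D"
    return StateIntervals(states=states, onsets=np.array(onsets),
                          offsets=np.array(offsets))


class TestAlignedRate:
    def _flat_rate_trace(self, intervals, dt=0.001, high=5.0):
        n = int(intervals.offsets[-1] / dt)
        t = (np.arange(n) + 0.5) * dt
        r = np.where(intervals.state_at(t) == "U", high, 0.0)
        return t, r

    def test_conditioning_keeps_flat_rate_flat(self):
        rng = np.random.default_rng(0)
        iv = _blocky_intervals(rng)
        t, r = self._flat_rate_trace(iv)
        ar = aligned_rate(t, r, iv, align="DU", tau_max=0.8)
        pos = ar.tau > 0.01
        assert np.nanmax(np.abs(ar.rate[pos] - 5.0)) < 1e-9
        neg = ar.tau < -0.01
        assert np.nanmax(np.abs(ar.rate[neg])) < 1e-9

    def test_unconditioned_average_shows_artifactual_decay(self):
        rng = np.random.default_rng(0)
        iv = _blocky_intervals(rng)
        t, r = self._flat_rate_trace(iv)
        ar = aligned_rate(t, r, iv, align="DU", tau_max=0.8, condition=False)
        far = (ar.tau > 0.5) & (ar.tau < 0.8)
        assert np.nanmean(ar.rate[far]) < 4.0  # period-length mixing bias

    def test_single_transition_returns_trace_segment(self):
        iv = StateIntervals(states=["D", "U"], onsets=np.array([0.0, 1.0]),
                            offsets=np.array([1.0, 2.0]))
        t = (np.arange(2000) + 0.5) * 0.001
        r = np.sin(t)
        ar = aligned_rate(t, r, iv, align="DU", tau_max=0.5)
        j = np.flatnonzero(np.isclose(ar.tau, 0.2))[0]
        i = np.argmin(np.abs(t - 1.2))
        assert ar.rate[j] == pytest.approx(r[i], abs=1e-6)


class TestOnsetOffset:
    def _gen(self, rng, ramp_U=0.0, ramp_D=0.0, n_units=48, duration=240.0):
        from updown.synthgen import SynthConfig, gen_population

        cfg = SynthConfig(n_units=n_units, duration=duration, ramp_U=ramp_U,
                          ramp_D=ramp_D, seed=int(rng.integers(2**31)))
        return gen_population(cfg)

    def test_flat_rates_give_null_difference(self):
        rng = np.random.default_rng(10)
        data, truth = self._gen(rng)
        res = onset_offset_analysis(data, truth.intervals, state="U",
                                    n_shuffles=200, seed=1)
        assert res.p_value > 0.05
        assert abs(np.mean(res.diffs)) < 0.15

    def test_compensated_ramps_widen_tails_but_null_mean(self):
        rng = np.random.default_rng(11)
        n = 48
        ramps = np.concatenate([np.full(n // 2, -0.6), np.full(n // 2, 0.6)])
        data, truth = self._gen(rng, ramp_U=ramps, n_units=n, duration=400.0)
        res = onset_offset_analysis(data, truth.intervals, state="U",
                                    n_shuffles=200, seed=2)
        lo, hi = res.null_band
        assert abs(np.mean(res.diffs)) < 0.1
        assert np.mean(res.diffs < lo) > 0.1 and np.mean(res.diffs > hi) > 0.1

    def test_down_recovery_ramp_detected(self):
        rng = np.random.default_rng(12)
        data, truth = self._gen(rng, ramp_D=1.2, duration=400.0)
        res = onset_offset_analysis(data, truth.intervals, state="D",
                                    min_period=0.5, n_shuffles=200, seed=3)
        assert np.mean(res.diffs) < 0
        assert res.p_value < 0.05


class TestAutocorrelogram:
    def test_sinusoid_closed_form(self):
        t = (np.arange(40_000) + 0.5) * 0.001
        r = 3.0 + np.sin(2 * np.pi * t)
        lags, ac = autocorrelogram(t, r, window_W=20.0, max_lag=1.2)
        assert ac[0] == pytest.approx(1.0)
        assert ac[np.argmin(np.abs(lags - 1.0))] == pytest.approx(1.0, abs=0.05)
        assert ac[np.argmin(np.abs(lags - 0.5))] == pytest.approx(-1.0, abs=0.05)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        t = (np.arange(60_000) + 0.5) * 0.001
        lags, ac = autocorrelogram(t, rng.normal(5, 1, t.size), max_lag=0.5)
        assert np.max(np.abs(ac[5:])) < 0.05

    def test_constant_trace_rejected(self):
        t = (np.arange(30_000) + 0.5) * 0.001
        with pytest.raises(ValueError):
            autocorrelogram(t, np.ones(t.size))


class TestSilenceDensity:
    def test_fully_silent_record_is_one_epoch(self):
        data = PopulationSpikeData(spikes=[np.empty(0)] * 4, duration=400.0)
        epochs = silence_density_epochs(data, min_len_s=300.0)
        assert len(epochs) == 1
        assert epochs[0][0] == 0.0 and epochs[0][1] >= 390.0

    def test_desynchronized_activity_yields_no_epoch(self):
        rng = np.random.default_rng(0)
        # sustained firing: silence density well below 0.4
        data = PopulationSpikeData(
            spikes=[np.sort(rng.uniform(0, 400, 4000)) for _ in range(20)],
            duration=400.0,
        )
        assert silence_density_epochs(data, min_len_s=300.0) == []

    def test_change_point_located_within_one_window(self):
        rng = np.random.default_rng(1)
        # silent first 350 s, dense afterwards
        busy = [np.sort(rng.uniform(350, 700, 3500)) for _ in range(20)]
        data = PopulationSpikeData(spikes=busy, duration=700.0)
        epochs = silence_density_epochs(data, min_len_s=300.0)
        assert len(epochs) == 1
        assert abs(epochs[0][1] - 350.0) <= 10.0
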