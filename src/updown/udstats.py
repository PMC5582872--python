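"""Interval and rate statistics for UP/DOWN sequences.

Implements the duration statistics (mean, CV with the population-variance
convention, CV2), maximum-likelihood gamma fits, the shuffle-corrected serial
correlogram of U/D duration sequences with pointwise and global confidence
bands, square-kernel population rates, transition-aligned rate averages with
the duration-conditioning rule, onset/offset rate comparisons, windowed
autocorrelograms and silence-density screening of synchronized epochs.

Pairing convention: the D period with the same index as U_i is the D that
*precedes* U_i (D_i = t_on,i - t_off,i-1), so the lag-0 correlation
Corr(U_i, D_i) relates each U to the immediately previous D, and lag +1 to
the following D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import PopulationSpikeData, StateIntervals

__all__ = [
    "DurationSequences",
    "DurationStats",
    "SerialCorrelogram",
    "AlignedRate",
    "durations",
    "duration_stats",
    "cv2_local",
    "gamma_fit",
    "serial_correlation",
    "population_rate",
    "aligned_rate",
    "onset_offset_analysis",
    "autocorrelogram",
    "silence_density_epochs",
]


@dataclass
class DurationSequences:
    """Paired, ordered U and D duration sequences (seconds).

    ``U[i]`` is the i-th UP duration; ``D[i]`` the duration of the D period
    immediately preceding it. ``u_onsets[i]`` is the onset time of U_i, used
    for windowed surrogate shuffling.
    """

    U: np.ndarray
    D: np.ndarray
    u_onsets: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.u_onsets = np.asarray(self.u_onsets, dtype=float)
        if abs(len(self.U) - len(self.D)) > 1:
            raise ValueError("U and D lengths may differ by at most 1")
        if np.any(self.U <= 0) or np.any(self.D <= 0):
            raise ValueError("durations must be positive")


@dataclass
class DurationStats:
    mean: float
    cv: float
    cv2: float


@dataclass
class SerialCorrelogram:
    """Shuffle-corrected correlogram Corr(U_i, D_{i+k}) with error bands."""

    lags: np.ndarray
    corr: np.ndarray           # surrogate-mean-corrected correlation per lag
    raw_corr: np.ndarray       # uncorrected Pearson correlation per lag
    pointwise_band: np.ndarray  # (2, n_lags): lower, upper 95% pointwise
    global_band: np.ndarray     # (2, n_lags): lower, upper global band
    global_coverage: float      # pointwise coverage % achieving the global band
    L_cov: int
    L_band: int


@dataclass
class AlignedRate:
    """Transition-aligned average rate with duration conditioning."""

    tau: np.ndarray
    rate: np.ndarray
    count: np.ndarray


def durations(intervals: StateIntervals) -> DurationSequences:
    """Extract paired U/D duration sequences from alternating intervals.

    Each U that is preceded by a complete D interval contributes a pair;
    leading and trailing partial periods are dropped.
    """
    if len(intervals) < 2:
        raise ValueError("need at least 2 intervals (one transition)")
    U, D, onsets = [], [], []
    for j in range(1, len(intervals)):
        if intervals.states[j] == "U" and intervals.states[j - 1] == "D":
            U.append(intervals.offsets[j] - intervals.onsets[j])
            D.append(intervals.onsets[j] - intervals.onsets[j - 1])
            onsets.append(intervals.onsets[j])
    if not U:
        raise ValueError("no complete D->U pairs in the interval series")
    return DurationSequences(U=np.array(U), D=np.array(D), u_onsets=np.array(onsets))


def duration_stats(seq) -> DurationStats:
    """Mean, CV and CV2 of a duration sequence.

    CV uses the population-variance convention Var = <x^2> - <x>^2; CV2 is the
    mean over consecutive pairs of ``2|x_{i+1} - x_i| / (x_{i+1} + x_i)``, a
    local irregularity measure insensitive to slow drifts.
    """
    x = np.asarray(seq, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m = float(np.mean(x))
    if m == 0:
        raise ValueError("zero mean duration")
    var = float(np.mean(x * x) - m * m)
    return DurationStats(mean=m, cv=float(np.sqrt(max(var, 0.0)) / m), cv2=cv2_local(x))


def cv2_local(seq) -> float:
    x = np.asarray(seq, dtype=float)
    if x.size < 2:
        raise ValueError("CV2 needs at least 2 consecutive values")
    num = 2.0 * np.abs(np.diff(x))
    den = x[1:] + x[:-1]
    return float(np.mean(num / den))


def gamma_fit(seq) -> tuple[float, float]:
    """Maximum-likelihood 2-parameter gamma fit; returns (shape, scale)."""
    x = np.asarray(seq, dtype=float)
    if np.any(x <= 0):
        raise ValueError("gamma fit requires strictly positive values")
    if x.size < 2 or np.var(x) == 0:
        raise ValueError("degenerate (constant) sample: gamma shape diverges")
    shape, _, scale = sps.gamma.fit(x, floc=0)
    return float(shape), float(scale)


# ---------------------------------------------------------------------------
# serial correlogram with surrogate correction


def _window_shuffled(values: np.ndarray, window_id: np.ndarray, L: int, rng) -> np.ndarray:
    """L random permutations of ``values`` restricted to equal-window blocks.

    Returns an (L, M) array. Implemented by arg-sorting window ids with a
    random tie-break key, which permutes uniformly within each window.
    """
    M = values.size
    keys = window_id[None, :] + rng.random((L, M)) * 0.5
    order = np.argsort(keys, axis=1)
    return values[order]


def _lagged_cov(u: np.ndarray, d: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Cov(u_i, d_{i+k}) per lag, NaN-pairs excluded, population convention."""
    mu = np.nanmean(u)
    md = np.nanmean(d)
    du = u - mu
    dd = d - md
    out = np.empty(lags.size)
    M = u.size
    for j, k in enumerate(lags):
        if k >= 0:
            a, b = du[: M - k], dd[k:]
        else:
            a, b = du[-k:], dd[: M + k]
        prod = a * b
        n_valid = np.sum(~np.isnan(prod))
        out[j] = np.nansum(prod) / n_valid if n_valid else np.nan
    return out


def _lagged_cov_matrix(U: np.ndarray, D: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Row-wise lagged covariances for (L, M) surrogate matrices."""
    mu = np.nanmean(U, axis=1, keepdims=True)
    md = np.nanmean(D, axis=1, keepdims=True)
    dU = U - mu
    dD = D - md
    M = U.shape[1]
    out = np.empty((U.shape[0], lags.size))
    for j, k in enumerate(lags):
        if k >= 0:
            prod = dU[:, : M - k] * dD[:, k:]
        else:
            prod = dU[:, -k:] * dD[:, : M + k]
        n_valid = np.sum(~np.isnan(prod), axis=1)
        out[:, j] = np.where(n_valid > 0, np.nansum(prod, axis=1) / np.maximum(n_valid, 1), np.nan)
    return out


def serial_correlation(
    seqs: DurationSequences,
    k_max: int = 7,
    outlier_sd: float = 3.0,
    shuffle_window_s: float = 30.0,
    L_cov: int = 1000,
    L_band: int = 10000,
    seed: int | np.random.Generator = 0,
    global_alpha: float = 0.05,
) -> SerialCorrelogram:
    """Shuffle-corrected serial correlogram of U/D durations.

    Steps: (i) values more than ``outlier_sd`` SD from their sequence mean are
    excluded; (ii) raw lagged covariances Cov(U_i, D_{i+k}); (iii) the mean
    covariance over ``L_cov`` surrogate series (order shuffled within
    ``shuffle_window_s`` windows) is subtracted, removing correlation induced
    by drifts slower than the window; (iv) pointwise 95% bands from ``L_band``
    surrogate correlograms; (v) global bands by widening the pointwise
    coverage until only ``global_alpha`` of surrogate correlograms cross at
    any lag.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    U = seqs.U.copy()
    D = seqs.D.copy()
    M = U.size
    if M < 10:
        raise ValueError("need at least 10 periods for correlation analysis")
    # (i) outlier exclusion
    for x in (U, D):
        mu, sd = np.mean(x), np.std(x)
        if sd > 0:
            x[np.abs(x - mu) > outlier_sd * sd] = np.nan

    window_id = np.floor(seqs.u_onsets / shuffle_window_s).astype(np.int64)
    # auto-widen windows holding fewer than ~3 periods on average
    while np.unique(window_id).size > 1 and M / np.unique(window_id).size < 3:
        shuffle_window_s *= 2.0
        window_id = np.floor(seqs.u_onsets / shuffle_window_s).astype(np.int64)

    lags = np.arange(-k_max, k_max + 1)
    raw_cov = _lagged_cov(U, D, lags)

    var_u = np.nanvar(U)
    var_d = np.nanvar(D)
    norm = np.sqrt(var_u * var_d)
    if norm == 0:
        raise ValueError("zero variance in durations")

    # (iii) surrogate-mean covariance
    surr_cov = _lagged_cov_matrix(
        _window_shuffled(U, window_id, L_cov, rng),
        _window_shuffled(D, window_id, L_cov, rng),
        lags,
    )
    mean_surr_cov = np.nanmean(surr_cov, axis=0)
    corr = (raw_cov - mean_surr_cov) / norm
    raw_corr = raw_cov / norm

    # (iv)-(v) bands from a larger surrogate ensemble, centered the same way
    surr_corr = (
        _lagged_cov_matrix(
            _window_shuffled(U, window_id, L_band, rng),
            _window_shuffled(D, window_id, L_band, rng),
            lags,
        )
        - mean_surr_cov
    ) / norm

    pointwise = np.nanpercentile(surr_corr, [2.5, 97.5], axis=0)

    def band_at(coverage: float) -> np.ndarray:
        half = (100.0 - coverage) / 2.0
        return np.nanpercentile(surr_corr, [half, 100.0 - half], axis=0)

    def crossing_frac(band: np.ndarray) -> float:
        out = (surr_corr < band[0]) | (surr_corr > band[1])
        return float(np.mean(np.any(out, axis=1)))

    lo, hi = 95.0, 100.0
    while hi - lo > 0.1:
        mid = 0.5 * (lo + hi)
        if crossing_frac(band_at(mid)) > global_alpha:
            lo = mid
        else:
            hi = mid
    coverage = hi
    return SerialCorrelogram(
        lags=lags,
        corr=corr,
        raw_corr=raw_corr,
        pointwise_band=pointwise,
        global_band=band_at(coverage),
        global_coverage=coverage,
        L_cov=L_cov,
        L_band=L_band,
    )


# ---------------------------------------------------------------------------
# rates


def population_rate(
    spikes: PopulationSpikeData, kernel_T: float = 100.0, dt_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous population rate by square-kernel counts.

    Per-unit spike counts in a sliding window of ``kernel_T`` ms are summed
    across units and normalized by ``T * N``; returns ``(t, R)`` with the time
    axis at ``dt_ms`` resolution (bin centers, seconds) and R in Hz.
    """
    if kernel_T <= 0:
        raise ValueError("kernel_T must be positive")
    if spikes.n_units == 0:
        raise ValueError("no units")
    dt_s = dt_ms / 1000.0
    n_bins = max(int(np.ceil(spikes.duration / dt_s)), 1)
    counts = np.zeros(n_bins)
    for s in spikes.spikes:
        idx = np.clip((s / dt_s).astype(np.int64), 0, n_bins - 1)
        np.add.at(counts, idx, 1.0)
    w = max(int(round(kernel_T / dt_ms)), 1)
    kernel = np.ones(w)
    summed = np.convolve(counts, kernel, mode="same")
    R = summed / (kernel_T / 1000.0) / spikes.n_units
    t = (np.arange(n_bins) + 0.5) * dt_s
    return t, R


def aligned_rate(
    t: np.ndarray,
    rate: np.ndarray,
    intervals: StateIntervals,
    align: str = "DU",
    tau_max: float = 1.0,
    condition: bool = True,
) -> AlignedRate:
    """Average rate aligned at DU or UD transitions, duration-conditioned.

    For each signed lag tau, a transition contributes only if the period
    containing that lag is longer than |tau| (e.g. for DU alignment and
    tau > 0, the following U must satisfy U_i > tau; for tau < 0 the
    preceding D must satisfy D_i > |tau|). This removes the artifactual decay
    caused by mixing periods of different lengths. Set ``condition=False`` to
    reproduce the unconditioned (biased) average.
    """
    dt = float(np.median(np.diff(t)))
    n_tau = int(round(tau_max / dt))
    tau = np.arange(-n_tau, n_tau + 1) * dt

    # collect (transition time, duration before, duration after)
    trans = []
    for j in range(1, len(intervals)):
        prev_s, cur_s = intervals.states[j - 1], intervals.states[j]
        kind = prev_s + cur_s  # "DU" or "UD"
        if kind != align:
            continue
        before = intervals.offsets[j - 1] - intervals.onsets[j - 1]
        after = intervals.offsets[j] - intervals.onsets[j]
        trans.append((intervals.onsets[j], before, after))
    if not trans:
        raise ValueError(f"no {align} transitions")

    rate_sum = np.zeros(tau.size)
    count = np.zeros(tau.size, dtype=np.int64)
    n = len(t)
    offsets_idx = np.arange(-n_tau, n_tau + 1)
    for t0, before, after in trans:
        i0 = int(round((t0 - t[0]) / dt))
        idx = i0 + offsets_idx
        ok = (idx >= 0) & (idx < n)
        if condition:
            # one-bin guard keeps the sampled bin wholly inside the
            # conditioning period despite onset-to-grid rounding
            ok &= np.where(tau >= 0, after > tau + dt, before > -tau + dt)
        rate_sum[ok] += rate[idx[ok]]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, rate_sum / np.maximum(count, 1), np.nan)
    return AlignedRate(tau=tau, rate=mean, count=count)


@dataclass
class OnsetOffsetResult:
    """Per-unit normalized onset-offset differences with shuffle nulls."""

    diffs: np.ndarray          # per-unit normalized onset - offset difference
    p_value: float             # two-sided Wilcoxon signed-rank across units
    null_band: tuple[float, float]   # 95% band of the pooled null per-unit diffs
    null_mean_band: tuple[float, float]  # 95% band of the null population mean
    excluded_units: list[int] = field(default_factory=list)


def onset_offset_analysis(
    spikes: PopulationSpikeData,
    intervals: StateIntervals,
    state: str = "U",
    window_on: tuple[float, float] = (50.0, 200.0),
    window_off: tuple[float, float] = (-200.0, -50.0),
    min_period: float = 0.5,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator = 0,
) -> OnsetOffsetResult:
    """Compare per-unit firing at period onset vs offset.

    For every period of ``state`` longer than ``min_period`` (s), each unit's
    rate is measured in the onset window (ms after onset) and the offset
    window (ms before offset), averaged across periods, normalized by the
    unit's overall time-averaged rate, and differenced. Significance of the
    population difference is a two-sided Wilcoxon signed-rank test; null
    bands come from shuffling onset/offset labels per (unit, period) while
    preserving unit and period indices.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    on_lo, on_hi = window_on[0] / 1000.0, window_on[1] / 1000.0
    off_lo, off_hi = window_off[0] / 1000.0, window_off[1] / 1000.0
    w_on = on_hi - on_lo
    w_off = off_hi - off_lo

    periods = [
        (intervals.onsets[j], intervals.offsets[j])
        for j in range(len(intervals))
        if intervals.states[j] == state
        and intervals.offsets[j] - intervals.onsets[j] > min_period
    ]
    if not periods:
        raise ValueError("no qualifying periods")

    n_units = spikes.n_units
    n_per = len(periods)
    onset_rates = np.empty((n_units, n_per))
    offset_rates = np.empty((n_units, n_per))
    for u, s in enumerate(spikes.spikes):
        for p, (t_on, t_off) in enumerate(periods):
            onset_rates[u, p] = (
                np.searchsorted(s, t_on + on_hi) - np.searchsorted(s, t_on + on_lo)
            ) / w_on
            offset_rates[u, p] = (
                np.searchsorted(s, t_off + off_hi) - np.searchsorted(s, t_off + off_lo)
            ) / w_off

    overall = np.array([len(s) / spikes.duration for s in spikes.spikes])
    keep = overall > 0
    excluded = list(np.flatnonzero(~keep))
    if not np.any(keep):
        raise ValueError("all units have zero overall rate")

    def per_unit_diffs(on_mat, off_mat):
        d = on_mat.mean(axis=1) - off_mat.mean(axis=1)
        return d[keep] / overall[keep]

    diffs = per_unit_diffs(onset_rates, offset_rates)
    if np.allclose(diffs, 0):
        p_value = 1.0
    else:
        p_value = float(sps.wilcoxon(diffs, alternative="two-sided",
                                     zero_method="wilcox").pvalue)

    null_diffs = np.empty((n_shuffles, diffs.size))
    null_means = np.empty(n_shuffles)
    for l in range(n_shuffles):
        swap = rng.random((n_units, n_per)) < 0.5
        on_s = np.where(swap, offset_rates, onset_rates)
        off_s = np.where(swap, onset_rates, offset_rates)
        d = per_unit_diffs(on_s, off_s)
        null_diffs[l] = d
        null_means[l] = d.mean()
    pooled = null_diffs.ravel()
    return OnsetOffsetResult(
        diffs=diffs,
        p_value=p_value,
        null_band=tuple(np.percentile(pooled, [2.5, 97.5])),
        null_mean_band=tuple(np.percentile(null_means, [2.5, 97.5])),
        excluded_units=excluded,
    )


def autocorrelogram(
    t: np.ndarray, rate: np.ndarray, window_W: float = 20.0, max_lag: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed, normalized autocorrelogram of a rate trace.

    The trace is cut into consecutive windows of ``window_W`` seconds; within
    each, the autocorrelation normalized by the window variance is computed
    (so AC(0) = 1 and AC(tau) is a Pearson correlation), then averaged across
    windows. Returns ``(lags_s, AC)``.
    """
    dt = float(np.median(np.diff(t)))
    per_win = int(round(window_W / dt))
    n_lag = int(round(max_lag / dt))
    if per_win <= n_lag:
        raise ValueError("window too short for requested max_lag")
    n_win = len(rate) // per_win
    if n_win == 0:
        raise ValueError("trace shorter than one window")
    acs = []
    for w in range(n_win):
        seg = rate[w * per_win : (w + 1) * per_win]
        seg = seg - seg.mean()
        var = np.mean(seg * seg)
        if var == 0:
            continue
        L = len(seg)
        ac = np.array([
            np.sum(seg[: L - k] * seg[k:]) / ((L - k) * var) for k in range(n_lag + 1)
        ])
        acs.append(ac)
    if not acs:
        raise ValueError("constant trace: autocorrelogram undefined")
    lags = np.arange(n_lag + 1) * dt
    return lags, np.mean(acs, axis=0)


def silence_density_epochs(
    spikes: PopulationSpikeData,
    bin_ms: float = 20.0,
    window_s: float = 10.0,
    density_thr: float = 0.4,
    sd_thr: float = 0.1,
    min_len_s: float = 300.0,
) -> list[tuple[float, float]]:
    """Screen for sustained synchronized-state epochs by silence density.

    Silence density is the fraction of ``bin_ms`` bins with zero population
    spikes, evaluated per consecutive ``window_s`` window. Maximal runs of
    windows with density above ``density_thr`` whose density SD stays below
    ``sd_thr`` and that last at least ``min_len_s`` are returned as
    ``(start_s, end_s)`` epochs.
    """
    if spikes.duration <= window_s:
        raise ValueError("record shorter than one window")
    dt_s = bin_ms / 1000.0
    n_bins = int(np.floor(spikes.duration / dt_s))
    counts = np.zeros(n_bins)
    merged = spikes.merged()
    idx = (merged / dt_s).astype(np.int64)
    idx = idx[idx < n_bins]
    np.add.at(counts, idx, 1.0)
    per_win = int(round(window_s / dt_s))
    n_win = n_bins // per_win
    dens = np.array([
        np.mean(counts[w * per_win : (w + 1) * per_win] == 0) for w in range(n_win)
    ])
    above = dens > density_thr
    epochs = []
    w = 0
    while w < n_win:
        if not above[w]:
            w += 1
            continue
        w2 = w
        while w2 + 1 < n_win and above[w2 + 1]:
            w2 += 1
        run = dens[w : w2 + 1]
        length = (w2 - w + 1) * window_s
        if length >= min_len_s and np.std(run) < sd_thr:
            epochs.append((w * window_s, (w2 + 1) * window_s))
        w = w2 + 1
    return epochs
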