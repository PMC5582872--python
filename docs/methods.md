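# Methods

`updown` models the alternation between active (UP) and quiescent (DOWN)
network states observed in cortical population activity during synchronized
brain states, and provides the detection and statistical machinery to
quantify that alternation in population spike trains. This note documents
the models, the numerical choices, and the limits of what the tests
demonstrate.

## Rate model (`updown.ratenet`, `updown.phaseplane`)

Two recurrently coupled populations with threshold-linear transfer
`phi_X(x) = g_X [x - theta_X]_+` and an additive adaptation current on the
excitatory population:

    tau_E r_E' = -r_E + phi_E(J_EE r_E - J_EI r_I - a + sigma xi_E)
    tau_I r_I' = -r_I + phi_I(J_IE r_E - J_II r_I + sigma xi_I)
    tau_a a'   = -a + beta r_E

Defaults: `tau_E = 10 ms`, `tau_I = 2 ms`, `tau_a = 500 ms`; couplings
`J_EE = 5, J_EI = 1, J_IE = 10, J_II = 0.5 s`; gains `g_E = 1, g_I = 4 Hz`;
`theta_I = 25 a.u.`; OU inputs with `sigma = 3.5`, `tau_ou = 1 ms`.
`beta = 0.5 s` is the generic default; the quantitative example point used
throughout the tests is `theta_E = 4.8, beta = 0.7` (`GREEN_SQUARE`), which
sits in the regime where both states are metastable and transitions are
noise-driven with adaptation modulating their timing.

Because `tau_E, tau_I << tau_a` the fixed-point analysis freezes adaptation:
with `J'_EE = J_EE - 1/g_E` and `J'_II = J_II + 1/g_I`, the UP point at
adaptation equilibrium is given in closed form (see `phaseplane.fixed_points`),
the DOWN point `(0,0,0)` is stable iff `theta_E > 0`, and four inequalities
partition the `(theta_E, beta)` plane into six regimes (single-state, both
metastable, mixed metastable/quasi-stable, and the adaptation-driven
oscillatory region). Boundary equalities resolve to the "more stable" label
so grid outputs are deterministic. The UP state is inhibition-stabilized
(`J'_EE > 0` with the determinant/trace conditions), which is why the
I rate, not the E rate, shows the pronounced decay during UP periods: the
adaptation-driven downward shift of the E nullcline moves the intersection
mostly along the steep I direction.

Numerics: classic RK4 at `dt = 0.2 ms`; the OU inputs are advanced by exact
discretization (update factor `exp(-dt/tau_ou)`) and held constant within
each RK4 step, so their stationary SD is `sigma` for any `dt`. Rates are
clipped at zero, consistent with the rectifying transfer. State detection
thresholds `r_E` at 1 Hz and absorbs runs shorter than 50 ms into their
neighbors, iterated shortest-first to a fixed point.

## Spiking network (`updown.spikenet`)

4000 excitatory and 1000 inhibitory leaky integrate-and-fire neurons,
all-to-all, current-based double-exponential synapses (inhibitory 1/1 ms,
excitatory 8/23 ms rise/decay, unitary area fixed to `tau_unit = 1 ms`),
per-presynaptic-neuron conduction delays (uniform 0-1 ms for E sources,
0-0.5 ms for I), spike-triggered AHP adaptation on E cells
(`beta_ahp/tau_a = 0.6 mV` per spike, `tau_a = 500 ms`), independent white
noise per neuron, and Poisson "kicks": brief (2 ms, 0.5 ms rise)
large-amplitude pulses delivered coherently to a fixed random 10% of each
population at 2.5 Hz, with amplitude halved while the network is UP
(`K = 220/110 mV` for E targets, `88/44 mV` for I targets). The online
UP/DOWN proxy for kick amplitude is the trailing 50 ms E population rate
against a 1 Hz threshold. Voltages: `V_L = -57.4`, thresholds `-45 / -43.9`,
resets `-51 / -49.9 mV`; membrane constants 20/10 ms; no refractory period.

Because the connectivity is all-to-all and delays attach to the presynaptic
neuron, the recurrent input reduces exactly to two population synaptic
variables driven by delayed population spike counts; the integration loop
(numba-jitted, `dt = 0.05 ms`) exploits this, and a per-presynaptic-neuron
oracle in the test suite verifies the collapse spike-for-spike. Membrane,
synaptic and AHP dynamics use exact exponential propagators with impulses
applied at step boundaries; the white noise uses the exact OU voltage
discretization, so `sigma_white` is the free-membrane voltage SD at any `dt`.

**Emergent dynamics at the default parameters.** At `sigma_white = 2.5 mV`
the quiescent state is deeply stable (rest sits 12.4 mV, ~5 SD, below
threshold) and each kick evokes a large synchronous volley followed by
~50-150 ms of reverberation through the slow excitatory synapses before the
network returns to silence. The detected "UP" periods of this configuration
are therefore kick-evoked transients (sub-second alternation with DOWN
durations set by the 2.5 Hz kick process), not a self-sustained active
attractor. This is a property of the equations, not of the integration: the
fast inhibitory population tracks excitation quasi-statically
(`s_I ~ J_IE s_E - (theta_I - V_L)`), capping the net recurrent excitatory
drive at `0.35 (theta_I - V_L) - 0.35 s_E < 4.7 mV` — far from the 12.4 mV
threshold distance — so the self-consistency map has a unique equilibrium
at every noise amplitude (verified over `sigma` 2.5-5.0 mV: the single
attractor slides continuously from silent to tonically active at ~1 Hz,
with no bistable window). A genuinely bistable low-rate active state would
require the determinant condition
`J_EE_eff * J_II_eff < J_EI * J_IE` together with the drive reaching
threshold, which these couplings exclude for any `J_EE`. All statistics the
package reports for this network are computed from the emergent transient
dynamics as they are.

The kick-free variant (`no_kick_variant`) disables kicks, depolarizes E by
5.6 mV and I by 6 mV, uses fast excitatory synapses (2/3 ms) and weaker
adaptation (200 mV·ms); transitions are then driven by the independent noise
alone, at the cost of unimodal membrane-potential distributions and
near-zero serial correlation between adjacent periods.

## Mean field (`updown.meanfield`)

The equilibrium rate of an LIF neuron is the first-passage (Ricciardi) rate,
evaluated as `r = [tau sqrt(pi) * int_a^b erfcx(-u) du]^{-1}` with
`a = (V_r - mu)/sigma`, `b = (theta - mu)/sigma`. In this form `sigma` is
the diffusion amplitude; the free-membrane voltage SD is `sigma/sqrt(2)`,
and the package passes `sqrt(2) * sigma_white` so the formula and the
simulator describe the same physical noise (verified against a brute-force
single-neuron simulation in the tests; quadrature tolerance 1e-10, asymptotic
log-space form beyond 15 SDs of threshold distance). Mean inputs follow the
population products `mu_E = V_L + N_E J_EE r_E tau_u + N_I J_EI r_I tau_u -
Ia` (the AHP current is subtracted, consistent with the membrane equation)
and analogously for I. The 2-D self-consistency is solved with a hybrid
root finder to 1e-8 Hz; stability uses the eigenvalues of the Jacobian of
the relaxation dynamics damped with the membrane time constants, and fold
locations are additionally diagnosed by branch termination.

**Known limitation.** The input SD in this approximation is the external
noise alone; recurrent input fluctuations — in particular the synchronous
volleys that actually sustain the simulated UP state — are not represented.
As a consequence the self-consistency map has a unique equilibrium at every
noise level for the default couplings, and the two-saddle-node bistability
seen in simulation is not reproduced by `bifurcation_scan`. The scan is
still the correct tool for configurations where the rate description holds;
its tests assert the realizable structure (continuous branch, monotone
decrease with Ia, a single crossing with the AHP equilibrium line
`Ia = beta_ahp * r_E`).

## Detection (`updown.detect`)

Population spike counts in 10 ms bins are modeled as a two-state hidden
Markov chain with Poisson emissions whose log-rate is a state-dependent
intercept plus a shared history term over the previous `J = 2` bins
(`log lambda_t = b_s + beta_h * sum_j y_{t-j}`). EM alternates exact
forward-backward E-steps (scaled, posteriors sum to one to 1e-12) with exact
transition updates and a damped Newton ascent on the emission parameters
(step halving guarantees the Q-function increases, hence a monotone
likelihood). Initial values: `alpha = 3`, `mu = -2` (log scale),
`beta_h = 0.01`, `P_DU = P_UD = 0.9`; these are starting points only — the
contract is the final labeling, which is canonicalized so the
higher-emission state is UP. Posteriors are thresholded at 0.5 and adjacent
same-state bins merged, so transition times are resolved at the bin size.
Explicit semi-Markov dwell-time distributions are not implemented; the
history term plus merging is the approximation used.

## Interval statistics (`updown.udstats`)

Durations pair each UP with the DOWN that precedes it, so the lag-0 serial
correlation relates U_i to the immediately previous D. CV uses the
population-variance convention; CV2 is the local pairwise measure
`mean 2|x_{i+1}-x_i|/(x_{i+1}+x_i)`, insensitive to slow drifts. Gamma fits
are 2-parameter maximum likelihood (`scipy.stats.gamma.fit` with the
location fixed at zero). The serial correlogram discards values more than
3 SD from the mean (correlation analysis only), subtracts the mean
covariance of surrogate series shuffled within 30 s windows (1000 by
default) to remove drift-induced correlation, and draws pointwise 95% and
global bands from a larger surrogate ensemble (10000 by default); the
global band widens the pointwise coverage by binary search (0.1%
resolution) until at most 5% of surrogate correlograms cross at any lag.
The calibration test shows the global band needs an adequately large
ensemble — a few hundred surrogates overfit the extreme percentiles and
inflate the false-positive rate.

Transition-aligned averages include a transition at signed lag tau only if
the period containing tau is longer than |tau| (plus a one-bin guard for
grid rounding), which removes the artifactual decay caused by averaging
periods of mixed length. Onset/offset comparisons use windows 50-200 ms
inside periods longer than 0.5 s, normalize each unit by its overall mean
rate, test the population with a two-sided Wilcoxon signed-rank, and build
null bands by shuffling onset/offset labels per unit and period.
Synchronized-state screening computes silence density (fraction of empty
20 ms bins) per 10 s window and returns runs above 0.4 with SD below 0.1
lasting at least 5 min.

## Synthetic generator (`updown.synthgen`)

The generator emulates what the statistics pipeline needs from a recording:
an alternating renewal state sequence with gamma durations (shape 2, scale
0.25 → mean 0.5 s, CV 0.71 per state), 64 units with lognormal UP rates
(mean 3.7 spikes/s, log-SD 0.5) and sparse DOWN firing (0.018 spikes/s),
optional linear within-state rate ramps per unit, optional slow sinusoidal
modulation of the mean durations, and optional adjacent-period coupling via
a latent adaptation level that relaxes toward 1 during U and toward 0 during
D with a 0.5 s time constant, scaling the next period's mean duration
(`exp(±c(a - 1/2))`). The gain `c = 1.2` (`CALIBRATED_COUPLING`) yields a
corrected lag-0 correlation near 0.2 with lag-1 slightly lower and higher
lags null — the magnitude and structure reported for cortical recordings.
Firing is conditionally Poisson given the state sequence; waveforms, LFP,
refractoriness and cell-type structure are not modeled, so passing tests
demonstrate correctness of the statistical machinery, not realism of the
spike trains.

## Problem sizes

The full-scale spiking simulation used by the acceptance script and the
corresponding tests runs 300 s of the 4000+1000-neuron network (the original
protocol used 5000 s), yielding roughly 300-350 periods of each state —
enough for duration statistics at the documented gamma-fit bias (shape
within ±15% at n = 300). Rate-model statistics use 120-300 s runs
(hundreds of periods); surrogate ensembles in tests are 100-2000 draws
(10000 at analysis scale). Every stochastic routine takes an explicit seed.
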