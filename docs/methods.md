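# Methods

`seqclock` implements a two-module spiking network that learns and replays
spatiotemporal sequences with purely local plasticity rules. This note
documents the model equations as implemented, the conventions adopted where
the formulation leaves room, the synthetic fixtures the tests run on, and
the known limitations of the implementation.

## Model

### Populations

Five neuron classes share a forward-Euler integrator (dt = 0.1 ms):

| class | role | dynamics | refractory |
|---|---|---|---|
| E | recurrent excitatory (N_E, in C clusters) | AdEx + adaptive threshold + adaptation current | 5 ms |
| I | recurrent inhibitory (N_I) | LIF, fixed threshold | 5 ms |
| R | read-out | AdEx threshold dynamics, no adaptation current | 1 ms |
| S | supervisor (one per R) | as R | 1 ms |
| H | interneuron (one per R) | LIF | 1 ms |

Membrane equation for excitatory classes (mV, ms, pF, pA):

    dV/dt = (E_L - V + Delta_T exp((V - V_T)/Delta_T)) / tau_m
            + g_exc (E_exc - V)/C + g_inh (E_inh - V)/C - a/C

with E_exc = 0 mV, E_inh = -75 mV. A spike is detected when the Euler
update diverges past 20 mV (the exponential argument is capped at 10 so
the divergent step stays finite); V resets to -60 mV and is clamped there
for the refractory period. The adaptive threshold jumps to V_T0 + A_T
(-42 mV) on a spike and relaxes with tau_T = 30 ms; the adaptation current
jumps by beta = 1000 pA (recurrent E only) and decays with tau_a = 100 ms.
Both continue to evolve during refractoriness (they are slow processes
distinct from the voltage clamp). LIF classes integrate the same equation
without the exponential and adaptation terms and spike on crossing
V_T0 = -52 mV. Default membrane parameters are the published table values
(see `seqclock.params`).

### Synapses

Each channel convolves its weighted input spike train with the normalized
difference-of-exponentials kernel K(t) = (e^(-t/tau_d) - e^(-t/tau_r)) /
(tau_d - tau_r) (excitatory 6/1 ms, inhibitory 2/0.5 ms), implemented as
two coupled first-order states with exact per-step exponential decay, so
the sampled conductance equals the kernel convolution of the delta train.
The kernel has unit time-integral: the stationary mean conductance is
weight x rate.

External inputs are Poisson. Counts per step are drawn as
Poisson(rate x dt) — the exact discretization of a merged large input
population; this also covers the 18 kHz training and up-to-10 kHz
supervisor channels where rate x dt > 1. A Bernoulli-thinning sampler with
a hard error at rate x dt >= 1 is provided as the low-rate contract
(`sample_poisson_spikes`).

### Plasticity

E->E and E->R synapses follow the voltage-based STDP rule

    dW/dt = -A_LTD s_pre(t) R(u - th_LTD)
            + A_LTP x_pre(t) R(V - th_LTP) R(v - th_LTD)

with u, v low-pass filters (10, 7 ms) of the postsynaptic voltage and x a
filter of the presynaptic train (3.5 ms recurrent, 5 ms read-out;
increment 1/tau_x so its stationary mean is the presynaptic rate).
Conventions adopted:

* **delta-train calculus.** s_pre is a spike delta train, so the
  depression term integrates to a per-spike impulse A_LTD R(u - th_LTD);
  the potentiation term is continuous and integrates with dt.
* **AP width.** The voltage seen by the rule (and by u, v) is the
  post-update membrane voltage clamped at 20 mV on the spike step and held
  there for a 2 ms action-potential window (`ap_width_ms`), after which the
  refractory value V_r is seen. The rule was fit to voltage traces that
  include the spike waveform; collapsing the AP to one 0.1 ms Euler step
  suppresses potentiation ~20-fold and no cluster structure forms on any
  realistic timescale. The 2 ms window is applied uniformly to all classes;
  for the 1 ms-refractory read-out neurons this makes supervised learning
  somewhat faster than the published operating point (see Limitations).
* **Read-out potentiation** is weight dependent,
  A_LTP = A (W_max - W)/(W_max - W_min), evaluated on the pre-update
  weight: a soft upper bound in place of normalization.
* **Normalization.** Incoming E->E weights are multiplicatively rescaled
  every 20 ms to their per-neuron target K (fixed at the incoming sum at
  initialization, expectation p N_E w0), then clipped to
  [W_min, W_max] in a single pass; masked (absent) synapses stay exactly
  zero forever.

I->E synapses follow the homeostatic rule

    dW/dt = A_inh (y_E - 2 r_0 tau_y) s_I(t) + A_inh y_I s_E(t)

with +1-increment rate traces y (tau_y = 20 ms) — the convention under
which the offset 2 r_0 tau_y is dimensionless and the fixed point sits at
the target rate r_0 = 3 Hz. The printed amplitude is not dimensionally
interpretable against pF weights; the default A_inh = 0.1 pF per spike is
chosen so the homeostat converges within an hour-long training session
(its documented role). Weights clip to [48.7, 243] pF.

Update order per step: conductances -> membranes -> spike detection ->
traces -> STDP and inhibitory impulses (clipped) -> normalization (every
20 ms).

## Protocols

**Stage 1 (clock training).** Clusters are stimulated in circular order:
10 ms of 18 kHz external excitatory Poisson drive per cluster, 5 ms gaps;
during each stimulation all other clusters receive an external inhibitory
input (4.5 kHz, 2.4 pF). The unstructured 4.5 kHz excitatory baseline
stays on by default (configurable); the inhibitory-plasticity and E->E
rules are active. Stretching the timing to 50/50 ms removes the pre/post
pairing between adjacent clusters and trains the slow-switching control.

**Stage 2 (read-out training).** Supervisor neurons receive Poisson input
whose rate follows the target signal (normalized to [0, 10] kHz);
interneurons receive a fixed 1 kHz drive; read-out synapses are plastic.
Playback is re-aligned to the clock at each cycle: a smoothed spike-count
detector on cluster 1 (EMA time constant 2 ms, threshold 10 % of the
cluster size) restarts the target whenever the first cluster activates.
After the learning time (default 960 s / N_C) supervisor and interneuron
inputs turn off and read-out plasticity is frozen.

**Targets.** Letter sequences (e.g. ABCBA) are piecewise-constant
one-hot channel signals, 75 ms and 10 kHz per letter. The complex-sequence
fixture is a parametric synthetic spectrogram: a sum of time-frequency
ridges with random onset, duration (40-180 ms), spectral width, frequency
drift and amplitude, normalized to a 10 kHz peak — it emulates the
multi-ridge, amplitude-varying structure of a birdsong spectrogram but
none of its harmonic stacking or temporal syntax, so tests passing on it
show the model can track multi-channel amplitude-varying targets, not that
it reproduces any particular song.

## Constructed clock fixtures

Training the recurrent network to a stable clock takes hours of simulated
time, so read-out and statistics experiments run on a hand-constructed
sequential matrix that emulates the trained outcome while preserving the
L1 operating point: background synapses at W_min, and the remaining
per-neuron budget K - p (N_E - 2 N_C) W_min split between intra-cluster
and cluster i->i+1 synapses with `intra_frac` (default 0.70) to the
former. At the default size this reproduces the published operating point
(period ~435 ms, cluster intervals ~14.5 ms tiling the cycle). For size
sweeps (N_C = 40...200) the uniform I->E weight is set to the
homeostatic lower bound — the operating point the inhibitory homeostat
relaxes a quiescent network toward — which makes reactivation reliable at
every size (periods varying < 20 % across N_C = 40/80/120).

Sizes other than the defaults scale initial weights and bounds by
sqrt(N_E_ref / N_E) and the connection probability so p N_C is constant;
the published large-network variant is available as an exact preset.

## Analysis conventions

* **ISI CV** per neuron over >= 3 spikes; note the estimator is biased low
  for few intervals, so spontaneous-state runs use 40-60 s of simulated
  time (~0.4 Hz excitatory rates).
* **Cluster activations** are detected from 2 ms-binned, 3 ms-smoothed
  per-cluster population rates thresholded at half that cluster's peak;
  runs shorter than 2 bins are discarded. The exact rule is a declared
  convention. Because consecutive cluster activations tile the cycle, the
  per-cluster *activation interval* is reported as period / C (the
  detected burst core at half-height is systematically ~3 ms shorter).
* **Period statistics** use successive reference-cluster onsets; cycles
  missing any cluster are excluded and counted as broken (the breakdown
  metric of the synfire-limit experiment).
* **Weber fit**: sigma_t = a sqrt(mu_t) through the origin by least
  squares.
* **Read-out rates**: spikes convolved with a unit-integral Gaussian;
  the ~12 ms width is interpreted as FWHM (sigma ~= 5.1 ms).
* **Spectra**: eigenvalues of the signed block matrix
  [[W_EE, -W_EI], [W_IE, -W_II]]; outliers are eigenvalues outside the
  circular-law bulk radius estimated from mean |lambda|^2.

## Problem sizes used in the test suite

Desk-scale runs: the spontaneous irregularity check uses the full
2400+600 network for 40-60 s; stage-1 structure formation uses C = 10
clusters of 20 neurons for 30 s of stimulation; clock statistics,
read-out learning and replay use constructed clocks at N_E = 1200-6000
for 3-14 s per run; the decoupling experiment uses C = 30, N_C = 40 for
4 s per arm. These sizes reproduce the qualitative regime; quantities
reported at full scale in the literature (e.g. the Weber coefficient
0.213 from 79 trials of an 80x80-cluster network) are only approached,
not matched, at desk scale.

## Known limitations

* **Feedforward structure from stimulation alone is weak.** With the
  published constants (tau_x = 3.5 ms, 5 ms gaps, ~6 ms conductance rise
  giving 8-12 ms response latency), spikes in adjacent stimulation windows
  are ~15 ms apart, so cross-window pairing is two orders of magnitude
  weaker than intra-window pairing. Thirty seconds of stimulation yield
  i->i+1 weights ~1.2x background (clusters themselves reach ~6x). The
  amplification loop that would consolidate the sequence — sequential
  reactivation strengthening the very weights that cause it — does not
  self-start from that bias in a 200-neuron network on desk timescales.
* **Sequential replay does not reinforce the off-diagonal here.** In the
  decoupling experiment the intact arm's i->i+1 mean relaxes slowly to a
  lower equilibrium instead of growing: at the depolarized balanced state
  (mean V ~ -59 mV > th_LTD = -70 mV) every presynaptic spike causes
  depression, which roughly cancels the transition potentiation, and the
  normalization squeeze from intra-cluster potentiation does the rest. The
  ablated arm degrades as expected.
* **Read-out operating point.** Under the 2 ms AP convention, replay
  drives ~3-4 read-out spikes per cluster activation (published: 2 +- 1),
  and recall after deleting 40 synapses per cluster is correspondingly
  more robust (~0.8 at N_C = 120 where ~0.5 is published; ~1.0 at
  N_C = 200 where ~0.8 is published). The replay order and the
  robustness ranking across cluster sizes are reproduced.
* Exact resume of a run requires the same Simulator instance; checkpoints
  restore configuration, weights, neuron states and the clock, but not
  synaptic conductances, plasticity traces or generator states.
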