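# Methods

## Model

`prnet` simulates a discrete-time binary recurrent network of `N = 100`
memoryless neurons under a k-winner-take-all (kWTA) constraint: at every
time step exactly the `k = 12` units with the highest membrane potential

    a_i(t+1) = sum_j W_ij x_j(t) + u_i(t+1) - T_i

fire (`x_i = 1`), all others stay silent. The hard kWTA constraint fixes
the population rate at `k/N` and stands in for an explicit inhibitory
population. Synaptic efficacies `W_ij` (pre `j` → post `i`) are bounded
to `[0, 1]` with zero diagonal; `T` are per-neuron firing thresholds;
`u` is the external drive.

Because every valid state has Hamming length exactly `k`, the state
space is the set of `C(N, k)` binary vectors with `k` ones, pairwise
Hamming distances are even, and two distinct valid states are at
distance ≥ 2. These facts are enforced after every operation and
exploited by the analysis code (distance features are computed via
inner products).

## Plasticity

Two local rules act during a plasticity phase (default 50,000 steps):

* **STDP** — antisymmetric, nearest-step causal:
  `dW_ij = eta (x_i(t) x_j(t-1) - x_i(t-1) x_j(t))`, `eta = 0.001`,
  hard-clipped to `[0, 1]`. When two neurons fire in both steps the two
  terms cancel exactly, so symmetric co-activation leaves weights
  untouched; only temporally *asymmetric* firing is imprinted.
* **IP** — homeostatic threshold regulation:
  `dT_i = eta_ip (x_i(t) - k/N)`, `eta_ip = 0.001`. The rule is
  subtractive and conserves the threshold sum exactly (to accumulated
  floating error below 1e-9 per step), a property the tests check.

Training conditions: `SIP` (both rules), `SP` (STDP only), `IP`
(a pre-phase of the same length with both rules, then a weight shuffle
that preserves the weight distribution while destroying its structure,
then an IP-only phase), `NONPLASTIC` (SP training, shuffle, frozen),
and `SP+IPTHRESH` (SP weights combined post hoc with thresholds from an
independent IP run, removing any interaction between the rules during
training).

### STDP acts on all ordered pairs (design choice)

The *initial* weight matrix is sparse: synapses exist with probability
0.10 and carry uniform `[0, 0.1]` efficacies. The plasticity rule
itself, however, is defined on every ordered pair of distinct neurons,
so potentiation can recruit synapses outside the initial support
(depression can prune them; the connectivity mask tracks the support of
`W`). This choice is load-bearing. The characteristic STDP-only outcome
— collapse onto a four-state, input-insensitive "minimal code" — arises
from a positive feedback loop: a slightly over-reinforced state
transition recruits recurrent drive for its successor state, which
makes the transition fire more often, which potentiates it further,
until the loop runs autonomously and ignores the input. If STDP is
confined to a fixed 10% mask, roughly 28% of the candidate successor
neurons have *no* synapse from the current winner set, the feedback
loop is frustrated, and the collapse becomes sporadic and lands on
arbitrary periods. With pair-unrestricted STDP the collapse is robust
across seeds and the learned cycle reflects the input structure
(period 4 under the Markov-85 drive, one vertex per symbol-state).
A mask-restricted variant remains available via
`NetworkConfig(stdp_respect_mask=True)`.

## Tasks and drive

Each input symbol owns a disjoint receptive field (15 neurons for the
two four-symbol tasks, 40 for the binary parity task, assigned as
contiguous index blocks by default); while a symbol is presented, every
neuron in its field receives a constant drive `A`, all others none.

* `RAND x 4`: i.i.d. uniform four-symbol input (memory probe).
* `Markov-85`: four symbols on the cycle A→B→C→D→A with transition
  probability 0.85, every other transition 0.05 (prediction probe). The
  chain is doubly stochastic, so its stationary law is uniform; the
  initial symbol is drawn from it to avoid burn-in.
* `Parity-3`: i.i.d. uniform binary input; the target is the XOR of
  three successive symbols (nonlinearity probe).

### Drive amplitude (design choice)

The drive amplitude is a free parameter of the model; the dynamical
regimes depend on where it sits relative to two scales: the initial
threshold spread (s.d. 0.1) and the saturated recurrent input (a few
potentiated synapses at weight 1). The default `A = 0.2` was chosen so
that (a) early in training the drive dominates winner selection, making
network states receptive-field-aligned and letting STDP imprint input
transitions, while (b) after potentiation the recurrent input can
override the drive, which is what lets the STDP-only network become
input-insensitive. Amplitudes at or below the threshold spread decouple
the early states from the input (the collapse then locks onto arbitrary
cycles); amplitudes approaching the saturated recurrent scale (≥ 0.5)
prevent input-insensitivity from ever emerging. Within the window
0.1–0.3 the qualitative results are insensitive to the exact value.

## Readouts

One multi-output linear classifier per time lag: states recorded over a
5,000-step training phase are regressed onto one-hot lagged-symbol
targets by ordinary least squares (`W_out = pinv(X) Y`, SVD cutoff
1e-10 — binary k-sparse state matrices are routinely rank-deficient),
then scored on the following 5,000-step testing phase (one contiguous
run) by row-wise winner-take-all over class scores. Between plasticity
and readout phases the network state is reset to a uniformly random
valid state — equivalently, a large perturbation — which is what kicks
jointly-trained (SIP) networks out of the input-insensitive attractor
into their input-sensitive regime; starting instead from the
end-of-plasticity state leaves them on the minimal-code attractor and
at chance performance.

## Information estimates

State entropy uses the exact plug-in estimator on discrete state
frequencies (for the four-state SP code the 2-bit value is exact;
the continuous k-NN route adds nothing there). Mutual information
between states and the three most recent inputs uses the first Kraskov
k-nearest-neighbor estimator (`k = 3` neighbors, Chebyshev metric,
reported in bits). Before estimation, states are projected onto the
principal components carrying 95% of the variance, and input windows
are embedded by assigning each of the four symbols a 3-bit even-weight
codeword (`000, 011, 101, 110` in alphabet order), so any two symbols
are at Hamming distance exactly 2 and a 3-step window is a 9-bit
vector. Exact repeats of discrete data break the estimator's
continuous-density assumption, so isotropic jitter of amplitude 1e-10
is added before the neighbor search; neighbor counting is done by
chunked brute-force Chebyshev distances, which outpaces KD-trees in the
high-dimensional joint space at these sample sizes. On fully
enumerable discrete joints the estimator agrees with the exact plug-in
value to well under 0.1 bit at 5,000 samples, and it recovers the
6-bit capacity of a lossless encoder of uniform 3-step windows to
better than 0.05 bit.

Sample sizes: 5,000 states suffice for every condition except the
IP-trained networks, whose state bandwidth is so high (≈ 89 principal
components at 95% variance) that MI estimates remain downward-biased
at desk scale; the package reports them as computed.

## Nonautonomous-dynamics analysis

Clamping one input makes the update a deterministic map on a finite
set, so cycle detection is exact: iterate 1,000 transient steps, then
index every visited state until the first revisit (the deterministic
lowest-index tie rule makes the clamped map a pure function of the
state). *Volumes of representation* are sampled from a single driven
trajectory by binning each visited state under its most recent
1..n inputs (a 100-step transient is discarded); on such single-run
samples the subset/union inclusion relations between volume orders
hold exactly, and the test suite treats any violation as an
implementation bug. Ellipsoid summaries project a state set onto a
fixed PCA basis (fitted on the pooled driven trajectory of the
analyzed run) and report coordinate means as center and either
coordinate standard deviations (default) or bootstrap percentiles
(5th/95th by default, 10,000 resamples) as semi-axes. Distance
features — the Hamming distances from each trajectory state to every
vertex of every clamped-input cycle — give a compressed geometric
description of the trajectory relative to the attractor landscape and
can be fed to the linear readouts in place of raw states.

## Noise model

Spike-flip noise with level `nu`: each active neuron is silenced
independently with probability `nu` and for each silenced neuron one
uniformly chosen silent neuron fires instead, preserving the kWTA
constraint. In the *robustness* protocol noise corrupts only the
testing phase of networks trained and fitted noiselessly, and the
reported quantity is the performance change relative to the matching
noiseless run, compared against the noisy-spike ratio. In the
*constructive* protocol the same noise level acts during plasticity,
training and testing; plasticity always sees the state the network
actually emitted (post-noise).

## Numerical and protocol choices

* Tie-breaking at the k-th potential: uniform among tied indices from
  the run's random stream during driven simulation; deterministic
  lowest-index in clamped-map analysis and anywhere reproducibility of
  a pure map is needed. After training, potentials are continuous and
  ties have measure zero.
* Plasticity phase 50,000 steps, training/testing phases 5,000 steps
  each, lags −8..+8, perturbation sizes {0, 2, 6, 12}, noise levels
  {0.01, 0.02, 0.05, 0.1, 0.2}: all configurable defaults. The
  IP-condition pre-phase reuses the same task generator with a fresh
  stream.
* The synthetic input generators *are* the study conditions: uniform
  and Markov-85 symbol streams are the exact processes the network is
  meant to adapt to, so passing tests speak to the model's behavior
  under these idealized drives, not to natural stimuli (no long-range
  correlations, no non-stationarity, no second-order structure).

## Known limitations

* Readout probes are linear and unregularized by design; no recursive
  or online variants.
* The MI of IP-condition networks is under-estimated at desk-scale
  sample sizes (their code needs ≈ 89 principal components).
* Basin structure is characterized operationally from sampled
  trajectories; no exhaustive state-space enumeration is attempted
  (`C(100, 12)` ≈ 1e15 states).
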