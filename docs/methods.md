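# Methods

## Model

`neurorc` treats a structural brain network as the fixed recurrent layer of a
reservoir computer. The reservoir is never trained; only a linear readout is.
This isolates the contribution of the wiring diagram: two networks driven by
identical inputs and read out by identically trained linear models differ in
performance only through their connectivity.

### Echo-state dynamics

The discrete-time reservoir updates as

    x(t) = f( x(t-1) W + u(t) M g ),    t = 1..T,   x(0) = 0

with `W[i, j]` the connection from node `i` to node `j` (row-state,
right-multiplication convention; stated once here to prevent silent
transposition bugs), `M` the C×n input map, `g` the input gain, and `f` one of
linear, tanh, sigmoid, ReLU or leaky ReLU applied elementwise. Inputs are
injected pre-activation, the standard echo-state formulation. There is no
leaky-integration term by default ("leaky ReLU" refers to the activation, not
to leaky integration); a `leak_rate` hook exists for experimentation but
defaults to the plain update. Trace row `t` is the state after consuming input
row `t`; `x(0)` is not recorded. This alignment convention is load-bearing
for the delay-line analysis below.

The global dynamical regime is set by rescaling the weight matrix so its
spectral radius — the largest absolute eigenvalue, not the largest singular
value — equals a chosen α: `W' = α W / ρ(W)`. Dynamics are stable (fading
memory) for α < 1, near-critical at α ≈ 1, and unstable/chaotic for α > 1.
Rescaling always targets α from the current matrix, so successive calls do
not compound. Nilpotent graphs (e.g. a pure feed-forward chain) have ρ = 0
and are rejected with a dedicated error, since spectral scaling is undefined
for them.

### Spiking dynamics

The continuous-time option is a leaky integrate-and-fire network,
Euler-integrated:

    tau_m dV_i/dt = -(V_i - v_rest) + I_syn,i + I_ext,i

with threshold-reset firing and an absolute refractory period. Each
presynaptic spike contributes a double-exponential current kernel

    w_ji (e^{-t/tau_decay} - e^{-t/tau_rise}) / (tau_decay - tau_rise)

implemented with two auxiliary exponential traces per neuron, which makes the
kernel exact up to the spike-time discretization. Time constants may be
per-neuron vectors (heterogeneous synapses); neurons flagged inhibitory have
the sign of their outgoing weights flipped. Defaults (dt = 0.1 ms,
tau_m = 20 ms, v_rest = v_reset = -65 mV, v_thresh = -50 mV, t_ref = 2 ms,
tau_rise = 0.5 ms, tau_decay = 5 ms) are standard cortical-neuron figures and
fully configurable. Task inputs at coarser timesteps are bridged by holding
each task step for a fixed number of integration steps (default 100, i.e.
10 ms per task step) and sampling the filtered trace at task-step boundaries.
Two closed forms anchor correctness: the constant-current inter-spike
interval `tau_m ln((I - (v_reset - v_rest)) / (I - (v_thresh - v_rest))) + t_ref`
and the kernel peak time `tau_r tau_d / (tau_d - tau_r) ln(tau_d / tau_r)`;
both are reproduced within 2·dt.

### Readout and scoring

Readout features are z-scored with training-set statistics and fitted by
ridge regression with an unpenalized intercept (delegated to scikit-learn;
an independent normal-equations solve is the test oracle). Classification
uses ridge-on-labels (±1 encoding, one-vs-rest beyond two classes) with
sign/argmax decisions — the classical "Ridge classifier". Default λ = 1.0,
exposed everywhere. λ = 0 falls back to a pseudoinverse solve with a
rank-deficiency warning.

Classification is scored with balanced accuracy (mean per-class recall) and
F1, on decision-epoch timesteps of test trials only; a trial-level variant
takes the majority vote over each trial's decision timesteps (ties to the
lower label, logged). Memory performance is Jaeger's memory capacity,
`MC = Σ_k corr(y_k, ŷ_k)²` over lags k = 1..K, with the per-lag curve kept
alongside; both MC and the mean per-lag squared correlation are exported
since either may be the quantity of interest.

## Tasks

All generators are pure functions of their parameters and a seed.

* **Perceptual decision making** — 3 channels: constant bias, and two noisy
  streams with generating means `m ± δ` (δ drawn per trial from the coherence
  set); report which stream is higher on average. Defaults: epochs
  fixation 3 / stimulus 10 / decision 3 timesteps, m = 0.5, coherences
  {0.1, 0.2, 0.4}, noise sd 0.2 — chosen so that reservoir accuracy is high
  but not saturated at 1.0.
* **Context-dependent decision making** — 7 channels: bias, a one-hot
  two-channel context cue held through the trial, and two stimulus pairs
  (both present every trial); the target follows only the cued pair. Note
  this task is *not* linearly separable in raw channel means (it has XOR
  structure in cue × stimulus-difference), which is exactly why a nonlinear
  reservoir expansion helps; the solvability ceiling is instead verified by
  thresholding the cued pair's mean difference, which labels all noiseless
  trials correctly.
* **Memory capacity** — one channel of i.i.d. Uniform[-1, 1] noise; targets
  are its lagged copies, k = 1..20 by default, with the first
  washout + max_lag = 120 timesteps masked out of scoring.

Trials are split 70/30 into train/test at the trial level (no trial straddles
the split); the single-trial memory task splits the time axis contiguously,
train first. Scoring is confined to decision-epoch timesteps via the
dataset's mask, so washout handling lives in the task, not the simulator.

## Workflow and statistics

`run_experiment` sweeps α × activation × realization. Every random choice
derives from one master seed through `SeedSequence`-based child seeds keyed
by role and realization index, so raising `n_realizations` never changes
earlier realizations, and the whole pipeline is bit-reproducible (CSV reports
included). Summaries are per-α means with 95% t-intervals across
realizations. The default α grid is 0.05..2.0 in steps of 0.05, spanning
stable through chaotic regimes.

The input map defaults to seeded uniform-random weights in [-1, 1] from each
channel to each input node. A uniform constant broadcast is available but is
a poor default for multi-channel tasks: it feeds every input node the channel
*sum*, and in both decision tasks the two stimulus streams sum to a constant
`2m`, cancelling the discriminative contrast entirely. Input nodes default to
a random 10% of nodes (or are selected by partition label); readout nodes
default to the complement.

**Null comparison.** Surrogate networks are built by Maslov–Sneppen double
edge swaps (10 swap attempts per edge by default) that reject self-loops and
multi-edges, preserving the binary degree sequence — in- and out-degrees for
directed networks, with undirected networks swapped on the upper triangle and
mirrored — and hence density exactly; the original weight multiset is then
permuted onto the rewired topology. Graphs too dense to admit any valid swap
yield a weight-permuted copy with a warning and a flag. Each null repeats the
identical experiment with the same master seed (matched datasets, a paired
design that removes dataset variance from the comparison). Significance is
the nonparametric `p = (1 + #{null ≥ empirical}) / (1 + n_nulls)` (mirrored
for the `less` alternative), so the smallest attainable p with 500 nulls is
1/501 ≈ 0.002. Calibration is verified empirically: when the "empirical"
network is itself drawn from the null generator, rejection at the 0.05 level
occurs at the nominal rate.

**Stratified readout.** With a node partition (e.g. intrinsic functional
networks), each module serves as an independent readout on the same simulated
trace. Differences across modules at a chosen α are tested with a one-way
fixed-effects ANOVA computed from standard sums of squares, with realizations
as the sample unit; a zero within-group mean square reports F = +inf with a
note rather than an error. The hand-rolled ANOVA exists because the degenerate
cases are part of the contract; scipy's `f_oneway` is the cross-check oracle.

## Synthetic networks

The generator provides directed/undirected weighted Erdős–Rényi graphs,
two-block (or k-block) modular graphs with separate within/between densities
and block partition labels, directed delay-line chains, and directed rings
(spectral radius exactly 1). These emulate the degree heterogeneity, weight
dispersion and modular structure relevant to the pipeline's statistics, but
not the geometric embedding, hub architecture, log-normal weight
distributions or hemispheric symmetry of empirical tract-tracing or
diffusion-MRI connectomes — so passing tests demonstrate the machinery's
correctness and calibration, not any claim about real brains. Empirical
connectomes enter through the same CSV/npy loaders whenever available.

A delay line with 10 edges (11 nodes) is the analytically solvable reservoir:
node k holds `u(t-k)`, so exactly lags 1..10 of a white-noise stream are
reconstructible and MC = 10. This fixes both the MC statistic and the
trace-alignment convention at once.

## Numerical choices and problem sizes

* Spectral radii come from dense eigendecomposition (`numpy.linalg.eigvals`);
  networks here are at most a few hundred nodes, where this is exact and cheap.
  Scaling accuracy is verified to 1e-9 relative against a power-iteration
  oracle.
* Divergence guard: unbounded activations abort with a diagnostic error when
  any |state| exceeds 1e6 (threshold configurable); bounded activations
  cannot diverge.
* Whether empirical weights should be log-transformed before spectral scaling
  is left to the user (apply any transform before construction); the package
  applies none silently.
* Self-loops are stripped at load with a logged count; negative weights are
  rejected unless explicitly allowed.
* Default experiment sizes in the test-suite and the reproduction script —
  e.g. 200 calibration repeats of 20-null mini-experiments on 24-node
  networks, and 20-realization sweeps on 100-node networks with T = 500 —
  were chosen as the smallest sizes at which the statistics of interest
  (calibration rate, regime ordering) are stable across seeds.

## Known limitations

* No output feedback (readout-to-reservoir loops), conduction delays, or
  spatial embedding.
* The spiking reservoir injects analog currents; spike-train input encoding
  is out of scope, and the inhibitory mask is a plain sign flip without
  interneuron-specific connectivity constraints.
* Only the three tasks above are built in; external supervised datasets can
  be supplied in the dataset interchange format (two CSV tables + JSON
  sidecar).
* Rewiring mixes by random swap attempts (10 per edge); for very sparse or
  near-complete graphs the surrogate distribution may be imperfectly mixed,
  and fully unswappable graphs degrade to weight permutation with a flag.
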