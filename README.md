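# neurorc

**Connectome-based reservoir computing.** `neurorc` implements biological
neural networks as artificial ones: an arbitrary weighted connectivity matrix
— an empirical connectome or a synthetic graph — is imposed as the *fixed*
recurrent layer of a reservoir computer, driven with cognitive-task input
streams, and read out by a trained linear model. Because only the readout is
trained, differences in task performance between networks are attributable to
their wiring, which makes the framework a tool for asking how connectome
topology confers computational capacity: across dynamical regimes, against
degree-preserving null networks, and across anatomically defined subsystems.

It is written for researchers in network neuroscience and reservoir
computing who want a small, fully reproducible pipeline rather than a
framework: plain NumPy/pandas/scikit-learn underneath, everything seeded,
everything exportable as tidy CSV.

## The model

The echo-state reservoir evolves as

```
x(t) = f( x(t−1) W + u(t) M g ),   x(0) = 0
```

where `W` is the connectome scaled so its spectral radius equals a control
parameter α (`W' = α W / ρ(W)`), `M` routes task channels to input nodes,
and `f` ∈ {linear, tanh, sigmoid, ReLU, leaky ReLU}. Dynamics are stable for
α < 1, near-critical at α ≈ 1, chaotic for α > 1. A leaky integrate-and-fire
reservoir with double-exponential synaptic filtering is available for
spiking dynamics. The readout is a ridge model (`λ = 1` by default) on
z-scored states of the readout nodes; classification tasks are scored with
balanced accuracy and F1, memory with Jaeger's memory capacity
`MC = Σ_k corr(y_k, ŷ_k)²`. Null networks are Maslov–Sneppen rewirings that
preserve density and the exact degree sequence, compared nonparametrically
with `p = (1 + #{null ≥ empirical}) / (1 + n_nulls)`. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
import neurorc as nr

c = nr.make_synthetic("random", 80, density=0.12, seed=42)
cfg = nr.ExperimentConfig(
    connectome=c, task="memory_capacity",
    alphas=(0.5, 0.9, 1.0, 1.5, 2.0), activations=("tanh",),
    n_realizations=10, T=500, max_lag=20, washout=100, seed=0,
)
curve = nr.run_experiment(cfg)
print(curve.summary.query("metric == 'memory_capacity'")
      [["alpha", "mean", "ci_low", "ci_high"]].to_string(index=False))
```

prints

```
 alpha     mean   ci_low  ci_high
   0.5 5.354413 5.281586 5.427239
   0.9 6.455899 6.294723 6.617076
   1.0 6.103412 5.959614 6.247211
   1.5 4.806432 4.750688 4.862176
   2.0 4.251728 4.182439 4.321016
```

i.e. on this 80-node random network the reservoir reconstructs about 6 of
the 20 probed lags of its white-noise input, memory peaks in the stable
regime near criticality (α ≈ 0.9–1.0) and degrades as dynamics turn chaotic
(α > 1) — the canonical stability-to-chaos trade-off. The confidence band is
a 95% t-interval over 10 independent task realizations. Comparing the same
network against 99 degree-preserving rewired nulls:

```python
comp = nr.null_comparison(
    nr.ExperimentConfig(connectome=c, task="memory_capacity", alphas=(1.0,),
                        n_realizations=3, T=300, max_lag=10, washout=50, seed=0),
    n_nulls=99, alpha_at=1.0)
print(f"empirical MC = {comp.empirical_value:.3f}, "
      f"null mean = {comp.null_values.mean():.3f}, p = {comp.p_value:.4f}")
```

```
empirical MC = 5.727, null mean = 5.867, p = 0.7000
```

— an Erdős–Rényi graph is statistically indistinguishable from its own
rewired nulls, as it should be: beyond degree sequence and density it has no
topology to lose.

The same pipeline is scriptable from the shell:

```bash
neurorc synth --kind modular --n 60 --seed 1 --out conn.csv --partition-out part.csv
neurorc run --task perceptual_dm --connectome conn.csv --alpha-grid 0.5,1.0,1.5 \
            --n-realizations 10 --n-trials 200 --seed 1 --out results/
neurorc nulls --task memory_capacity --connectome conn.csv --alpha-grid 1.0 \
              --n-nulls 100 --seed 1 --out results_nulls/
neurorc stratify --task memory_capacity --connectome conn.csv --partition part.csv \
                 --modules M1,M2 --alpha-grid 1.0 --seed 1 --out results_strat/
```

All outputs are tidy CSV plus a JSON summary (and optional figures with
`--figures`); repeating any invocation with the same seed reproduces the
CSVs byte for byte.

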