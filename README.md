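# snapnet

Bayesian nonparametric inference of gene-state reaction networks from
snapshot count data (e.g. smFISH-like RNA counts from fixed cells).

A gene network is a set of discrete gene states with per-state RNA
production rates, fully connected switching rates, and a global
degradation rate. Given ensembles of single-cell counts collected at a
few fixed times, `snapnet` samples the joint posterior over

* the **number of states** `N` — via a Beta-Bernoulli process prior over
  `L` candidate states (binary loads + success probabilities),
* all **kinetic rates** — log-normal priors, sampled in log space,
* the shared **initial gene state**.

The likelihood integrates the chemical master equation over a truncated
(finite-state-projection) state space; the sampler is a Gibbs sweep
(loads → success probabilities → initial state → rates) whose rate block
mixes adaptive Metropolis-Hastings with intermittent Strang-split
Hamiltonian Monte Carlo, embedded in adaptive parallel tempering with
randomized pairwise swaps. A Gillespie simulator generates benchmark
snapshot datasets with ground-truth sidecars.

## CLI

```sh
# simulate a benchmark dataset (CSV + ground-truth sidecar)
snapnet simulate --preset two_state --seed 1 --out two_state

# run inference (config optional; flags override file values)
snapnet infer --data two_state.csv --seed 1 --sweeps 2000 --out runs/demo
snapnet infer --data two_state.csv --ablation no_pt --fix gamma=1.0 --out runs/ablation

# summarize a trace: burn-in, credible intervals, posterior over N, figures
snapnet report --trace runs/demo/trace.csv --out runs/demo/report
```

Presets: `one_state`, `two_state`, `three_state`. Ablations: `full`
(AMH + HMC within PT), `fixed_proposals`, `no_pt`.

A YAML config mirrors the module settings (`prior`, `sampler`, `hmc`,
`pt`, `model`, `run` sections); see `snapnet.config.RunConfig`.

## Package layout

| module | contents |
| --- | --- |
| `network_model` | `NetworkState`, rates, truncated CME generator, label canonicalization |
| `cme_likelihood` | CME propagation (structured uniformization + fallbacks), snapshot likelihood, finite-difference gradients |
| `priors` | log-normal rate priors, Beta-Bernoulli process prior |
| `rate_samplers` | adaptive MH (running covariance + jitter), Strang-split HMC |
| `nonparametric_gibbs` | the Gibbs sweep over loads / q / sigma* / rates |
| `parallel_tempering` | tempered ensemble, randomized swaps, ladder adaptation |
| `synthetic_data` | Gillespie endpoint simulator, snapshot dataset assembly, presets |
| `diagnostics` | trace store, autocorrelation/IACT, burn-in, posterior summaries, ablation report |
| `benchmarks` | seeded benchmark replicates + convergence criterion |
| `config`, `cli` | YAML run configuration and the `snapnet` command |
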