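# seedswitch

A stochastic bistable-switch model of seed germination timing. The package
implements a four-variable hormone network — abscisic acid (ABA), gibberellin
(GA), a lumped germination inhibitor ("Integrator") and a sowing signal (Z)
coupled through Hill-type regulation — and everything needed to study it:

- **`seedswitch.model`** — parameters (immutable, with reference defaults),
  state, Hill regulatory functions, deterministic drift and chemical-Langevin
  diffusion amplitudes (noise intensity 1/V).
- **`seedswitch.steady`** — fixed points of the reduced scalar Integrator
  equation (geometric bracketing + Brent refinement), stability labels,
  nullcline sections, and classification into monostable / bistable /
  tristable regimes with biological-relevance flags (instantaneous
  germination, deterministic non-germination, germination without the
  sowing-induced GA rise).
- **`seedswitch.simulate`** — stochastic Heun integration (Itô, absorptive
  barrier at 0, dt = 0.1, stop at t = 1000 by default) of seed ensembles;
  germination is the first passage of the Integrator below a threshold, and
  seeds that never cross are censored.
- **`seedswitch.stats`** — germination-time traits (CV = sd/mean, mean, mode,
  % germination) from simulated times or day-binned count tables, with the
  <10-germinated plate filter, the 1%-germination reporting filter and
  unweighted replicate averaging per line.
- **`seedswitch.scan`** — 1D/2D log-spaced parameter scans and exogenous
  ABA/GA dose–response experiments with reproducible per-point RNG streams.
- **`seedswitch.synth`** — synthetic experimental-style datasets (lines ×
  replicate plates × daily counts) spanning peaked, long-tailed and bimodal
  germination phenotypes; `reference_design()` bundles a 14-line example.

## CLI

All subcommands accept `--params FILE` (flat YAML, keys like `theta_I_ABA`;
omitted keys fall back to the reference defaults) and `--seed` for full
reproducibility.

```sh
# regime of the high-variability parameterization
seedswitch regimes --theta-i-aba 5.8            # -> bistable

# stochastic ensemble, per-seed germination times + provenance sidecar
seedswitch simulate --n-seeds 1000 --seed 1 --out times.csv

# 1D scan of the ABA regulatory threshold
seedswitch scan --axis theta_I_ABA 5.8 7.0 4 --n-seeds 400 --out scan.csv

# exogenous hormone dose responses for low/high-variability classes
seedswitch dose-response --hormone ABA --doses 0,1.5,2.5 --out dr.csv

# synthetic count data and trait statistics
seedswitch synth --seed 0 --out counts.csv
seedswitch stats --counts counts.csv --min-plate 10 --out lines.csv
```

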