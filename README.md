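# fcmix

Quantitative modeling of **mixed-composition IgG immune complexes**: how
antibody Fc subclass mixtures bind Fcγ receptors, how multivalent binding
screens refine Fc–FcγR affinity estimates, and how model-predicted receptor
crosslinking on effector cells translates into in vivo target-cell
depletion.

The package is aimed at quantitative immunologists and systems biologists
working with immune-complex binding assays (CHO cell panels displaying
single FcγR variants, bead- or antigen-scaffolded IgG multimers) and
antibody effector-function readouts.

## The model

An immune complex carries `f` IgG Fc units drawn from a mixture with
monomer proportions `Cᵢ` (`ΣCᵢ = 1`). Monovalent binding to receptor `j`
has association constant `Ka,ij` (M⁻¹); each bond after the first forms
with constant `Kx*·Ka,ij`, where `Kx*` is the crosslinking constant. With
`φᵢⱼ = Req,j·Ka,ij·Kx*·Cᵢ` (and `φᵢ₀ = Cᵢ` for the unbound slot), the
configuration distribution is multinomial and sums in closed form:

    Lbound   = (L₀/Kx*)·(Φ^f − 1)                 bound complexes
    Rbound,n = (L₀·f/Kx*)·φₙ·Φ^(f−1)              bound receptor n
    Rmulti,n = (L₀·f/Kx*)·φₙ·(Φ^(f−1) − 1)        crosslinked receptor n

with `Φ = Σφᵢⱼ` and `φₙ = Σᵢφᵢₙ`. Free receptor `Req` solves the mass
balance `Rtot,n = Req,n + Rbound,n(Req)` (reduced to one scalar root in
`Φ`). An exhaustive configuration-enumeration oracle verifies the closed
forms for integer valency.

On top of the binding core:

- **`fcmix.priors` / `fcmix.inference`** — Bayesian affinity refinement
  from binding screens. Log-normal affinity priors are parameterized by
  documented value (mode) and standard error (interquartile range), with
  non-binders clipped to mode 10⁴ M⁻¹ / IQR 10⁵ M⁻¹; receptor abundances
  get log-normal MLE priors from expression replicates;
  `f₄ ~ logN(log 4, 0.2)`, `f₃₃ ~ logN(log 33, 0.2)`,
  `Kx* ~ logN(log 6.31·10⁻¹³, 2.0)`. Measurements enter through a
  log-normal likelihood with per-day scale factors. Three regimes: all
  parameters pinned, everything-but-affinities fitted, or affinities fitted
  from single-subclass rows only (mixtures held out for validation).
  Sampling is ensemble MCMC initialized from a L-BFGS-B MAP estimate.
- **`fcmix.depletion`** — in vivo regression: effector-cell activity
  `xₙ = max(Σᵢ pᵢ·Rmulti,i, 0)` with `p = +1` for activating receptors and
  `−1` for the inhibitory FcγRIIB, linked to depletion through the
  exponential CDF `ŷ = 1 − exp(−Σₙ wₙ·xₙ)`; nonnegative cell-type weights
  `wₙ` are fitted by MCMC under a beta observation model.
- **`fcmix.stats`** — PCA variance explained via Frobenius reconstruction,
  one-way ANOVA variance partition, intervalency (33:4) binding ratios,
  Spearman tests with the t-approximation.
- **`fcmix.simulate`** — synthetic data for every stage with recorded
  ground truth: the 432-condition factorial design (6 receptors × 2
  valencies × 6 subclass pairs × 6 compositions), forward-simulated screens
  with per-day geometric-mean normalization, expression replicates, and a
  humanized-mouse-style depletion study.

## Worked example

```python
import numpy as np
from fcmix import simulate as sim
from fcmix.priors import build_priors
from fcmix.inference import FitConfig, sample_posterior

truth = sim.default_truth(seed=1)
design = sim.generate_design()
pure = design[design.frac1.isin([0.0, 1.0])]
table = sim.simulate_binding_screen(truth, pure.reset_index(drop=True), replicates=3)
priors = build_priors(sim.documented_affinity_table(),
                      sim.simulate_expression_replicates(truth))
cfg = FitConfig(regime="fit_affinity", chains=2, draws=500, warmup=500, seed=1)
samples = sample_posterior(table, priors, cfg)
summary = samples.summary().set_index("parameter")
med = summary.loc["logka:IgG1:FcgRIIA-131H", "median"]
print(f"IgG1-FcgRIIA-131H: posterior median Ka = {med:.3g} M^-1 "
      f"(truth {truth.affinities.ka[0, 1]:.3g})")
print(f"max R-hat = {samples.max_rhat:.3f}")
```

Output:

```
IgG1-FcgRIIA-131H: posterior median Ka = 5.07e+06 M^-1 (truth 5.2e+06)
max R-hat = 1.047
```

The posterior median recovers the generating affinity within a few
percent; `max R-hat` near 1 indicates the two independently seeded
ensembles agree.

A command-line interface wraps the stages: `fcmix simulate`,
`fcmix fit-affinities`, `fcmix predict`, `fcmix regress`,
`fcmix summarize` (see `--help` on each).

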