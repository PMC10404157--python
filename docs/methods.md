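# Methods

## Equilibrium model of multivalent immune-complex binding

A complex of effective valency `f` (a positive real; the engagement
capacity of a preparation need not be integer) at solution concentration
`L₀` binds a cell displaying receptor types `j = 1..NR` at `Rtot,j`
copies. Its monomer Fc species `i = 1..NL` are assorted randomly with
proportions `Cᵢ`. The first bond of a complex forms with the monovalent
association constant `Ka,ij`; every subsequent bond forms with
`Kx*·Ka,ij`. `Kx*` (printed unit cell·M) is treated as an opaque scale —
the propensity conversion between solution binding and surface
crosslinking — with default `6.31·10⁻¹³`. The model is an equilibrium
description: no kinetics, no geometric or steric structure of the antigen
scaffold.

Writing `φᵢⱼ = Req,j·Ka,ij·Kx*·Cᵢ` and `φᵢ₀ = Cᵢ`, the relative abundance
of a binding configuration `q` (bond counts per species × receptor plus
unbound slots, summing to `f`) is `multinom(f;q)·(L₀/Kx*)·Πφ^q`. All
macroscopic quantities used downstream are closed-form sums of this
distribution (`Φ = Σφᵢⱼ`, `φₙ = Σᵢφᵢₙ`):

- bound complexes `Lbound = (L₀/Kx*)(Φ^f − 1)` — the quantity assumed
  proportional to the anti-IgG fluorescence readout of a binding screen;
- bound receptor `Rbound,n = (L₀f/Kx*)φₙΦ^(f−1)`;
- crosslinked receptor `Rmulti,n = (L₀f/Kx*)φₙ(Φ^(f−1) − 1)` — receptor
  inside complexes holding ≥ 2 bonds, the proxy for activation-competent
  receptor.

The measured fluorescence could equally be read as bound IgG monomers
rather than bound complexes; we model `Lbound` (consistent with prior use
of this model family), and any proportionality constant is absorbed by the
batch-scale nuisance parameter of the inference, so the choice affects
interpretation more than fit.

**Solving for free receptor.** Conservation (`Rtot = Req + Rbound(Req)`)
is an NR-dimensional system, but given `Φ` it separates:
`Req,j = Rtot,j/(1 + (L₀f/Kx*)aⱼΦ^(f−1))` with `aⱼ = Kx*ΣᵢCᵢKa,ij`.
Substituting back yields a single scalar equation in `Φ` whose right side
is strictly decreasing, so the root on `[1, 1 + Σaⱼ·Rtot,j]` is unique.
We solve it with Brent's method at relative tolerance ~9·10⁻¹⁶ (machine
limit); solved states satisfy conservation to ~10⁻¹⁴ relative, and the
solver raises if the residual exceeds 10⁻⁸. For the screen likelihood
(single-receptor cell lines, thousands of evaluations) the same scalar
equation is solved by 90-step bisection vectorized across conditions.
This scalar-root formulation replaced a direct multidimensional solve
because free-receptor counts span decades and the reduced problem is
bracketed and monotone — no initialization or conditioning concerns.

**Verification oracle.** For integer `f` with small `NL·NR`, the package
enumerates every configuration exhaustively (guard: 10⁶ configurations)
and compares the weighted sums against the closed forms; agreement is at
rounding error (~10⁻¹⁴ relative, tolerance 10⁻⁸).

A note on the monovalent limit: because `L₀` is held fixed (no ligand
depletion), the `f = 1, NL = NR = 1` mass balance is linear,
`Req = Rtot/(1 + L₀Ka)` — not the quadratic form that arises when the
ligand also depletes. Tests verify against the model's own closed form.

## Prior construction

Affinity priors are log-normal with **mode = documented Ka** and
**IQR = documented standard error**. Given (mode, IQR) the parameters
follow from `mode = exp(μ − σ²)` and
`IQR = exp(μ)·2·sinh(zσ)·exp(σ²)` with `z = Φ⁻¹(0.75)`; the substitution
`μ = log mode + σ²` leaves one strictly increasing function of σ, solved
by Brent to 10⁻¹⁴. Documented non-binders (Ka or SE of 0, or missing) are
clipped to mode 10⁴ M⁻¹ and IQR 10⁵ M⁻¹ *before* solving — this keeps
nominally non-binding interactions estimable with a deliberately wide
prior rather than excluded, which is what lets a binding screen revise a
"non-binder" upward.

Expression priors are log-normal MLE fits to replicate abundance
measurements per cell line (sample mean and 1/n-SD of logs), with a floor
of 0.01 on the log-scale spread so identical replicates still give a
proper prior. Effective-valency priors `f₄ ~ logN(log 4, 0.2)`,
`f₃₃ ~ logN(log 33, 0.2)` and `Kx* ~ logN(log 6.31·10⁻¹³, 2.0)` are fixed.

## Screen inference

**Likelihood (a modeling choice; the upstream description of this assay
family does not specify one).** `log RFU ~ Normal(log scale_day +
log Lbound, σ)` with one free positive scale per assay day and a single
shared σ. Rationale: the data are geometric-mean normalized per day, so
only a per-day scale links model units to normalized fluorescence, and
multiplicative error is the natural model for fluorescence intensities.
Day scales get a nearly flat log-normal prior (`logN(0, 10)`) and σ a
`logN(log 0.2, 1)` prior. `f₄/f₃₃/Kx*` are shared globally across
receptors and days (not stratified).

**Regimes.** `fixed_all` pins everything (documented affinities at their
prior modes; all other parameters at the mode of their log-scale Normal
prior, i.e. nominal valencies, default Kx*, unit scale) and is purely
predictive. `fit_nonaffinity` samples everything except affinities.
`fit_affinity` additionally samples affinities but its likelihood sees
only pure-composition rows — mixtures are reserved to validate the
posterior predictive. Pinning conventions make the regimes nest exactly.

**Computation.** All parameters are sampled as logs. MAP is L-BFGS-B with
numeric gradients, warm-starting day scales from prior-mode residuals. The
sampler is ensemble MCMC (emcee's affine-invariant walkers; walker count
`max(2·ndim + 2, 48)`): each requested "chain" is an independently seeded
ensemble started in a tight ball around the MAP; after the warmup steps,
walker states are flattened until the requested number of draws per chain
is retained. Split R-hat across chains (arviz) above 1.05 raises a
warning, not an error. A hard support box ±50 log-units around the pinned
values guards against overflow during line searches. Default sampler
settings are 4 chains × 1000 draws after 1000 warmup steps; the test suite
and acceptance script run the reduced 2 × 500 preset, which already
recovers synthetic affinities to ≲ 0.1 log₁₀.

**Identifiability.** Two structural limits are worth knowing. (1) An exact
ridge couples a joint rescaling of all affinities with an inverse change
of `Kx*` and the day scales; the `Kx*` prior (σ = 2) fixes the absolute
level only weakly, so absolute affinities inherit that uncertainty while
relative affinities are data-determined. (2) Interactions that saturate
the receptor pool at the assay concentration (e.g. Ka ≳ 10⁷ M⁻¹ at 1 nM)
have near-zero elasticity of bound complexes with respect to Ka, and their
posterior tracks the prior. Conversely, high-valency arms are
superlinearly sensitive to weak affinities, which is why valency-33 data
constrain low-affinity interactions (Ka ~ 10⁴–10⁵) more tightly than
valency-4 data — the avidity advantage the screen design exploits.

## Depletion regression

Effector-cell activity is `xₙ = max(Σᵢpᵢ·Rmulti,i, 0)` with `pᵢ = +1`
(activating) or `−1` (inhibitory FcγRIIB), `Rmulti` computed at 4-valent
complexes and 1 nM (both config-overridable). Depletion is
`ŷ = 1 − exp(−Σwₙxₙ)`: the survival-analysis view in which every target
cell has equal clearance hazard over the experiment. Cell weights absorb
effector abundance, so no per-organ cell counts enter.

Fitting choices the source description leaves open, made here as package
design: weights are constrained **nonnegative** via log-normal priors
(σ = 2, location set so a weight of that size alone yields ~50% depletion
of the median-activity cell — a scale-free centering), because a negative
clearance potency is uninterpretable under the survival link. The
observation model is a **beta** distribution centered on ŷ with a fitted
concentration (`logN(log 10, 1)` prior), reflecting bounded fractions with
large experiment-to-experiment spread. Sampling is the same MAP + ensemble
MCMC machinery (5 free parameters).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
a full 432-condition factorial (6 receptor variants × valencies {4, 33} ×
6 subclass pairs × composition series {100, 90, 66⅔, 33⅓, 10, 0}%), 3
technical replicates, multiplicative log-normal noise at 20% CV
(`σ = √log(1+CV²)`), conditions randomized across 3 assay days with
log-normal day scales centered so raw signals sit in the low thousands,
then per-day geometric-mean normalization to 1.0. Ground-truth affinities
default to documented literature-scale constants with the non-binder
clips applied, so synthetic screens show the real screens' qualitative
signatures: binding tracks affinity, valency-33 ≥ valency-4 everywhere,
and the 33:4 ratio is largest for weak interactions. Every dataset carries
its generating parameters as a JSON-serializable manifest and is
bit-reproducible from its seed.

The synthetic effector-cell panel (classical monocytes, non-classical
monocytes, neutrophils over FcγRI/FcγRIIA-131H/FcγRIIB/FcγRIIIA-158F) was
designed so each cell type is dominated by a different receptor and
contributes materially to the predictor for at least one IgG subclass;
this makes the cell-weight ranking identifiable from a 4-treatment study,
which is the property the depletion recovery harness exercises. True
weights (2·10⁻⁴, 5·10⁻⁵, 10⁻⁵) put predicted depletion in the 0.1–0.5
range where a beta observation model (concentration 40, i.e. donor-level
scatter of ±7 points) neither floors nor saturates.

What passing tests on synthetic data do **not** show: recovery of the real
study's refined affinity values (that requires the deposited measurements,
out of scope here); robustness to additive background fluorescence,
detection floors, day-receptor interactions, or donor genetic structure —
none of which the generator simulates; or correctness of the anti-IgG
readout interpretation (complexes vs monomers, above).

## Numerical choices and degenerate inputs

- Equilibrium root: Brent on the bracketed scalar slot-sum; vectorized
  90-step bisection in the likelihood path (branch-free, deterministic).
- `L₀ = 0` or all-zero affinities short-circuit to the unbound state.
- Prior solve rejects (mode, IQR) pairs with no positive-σ solution.
- ANOVA fraction defined as 0 for an all-constant table; the SS-ratio
  estimator of the between fraction is biased upward relative to the
  population variance fraction (expectation ≈ 0.81 when the population
  fraction is 0.75 at 50 conditions × 4 replicates) — tests compare
  against the analytic expectation of the estimator.
- PCA matrices are column-centered before decomposition (standard
  practice; a flag disables it); variance explained equals the cumulative
  squared-singular-value fraction.
- Spearman ties get average ranks; p-values use the t approximation.
- Observed depletion fractions are clipped into (10⁻⁴, 1−10⁻⁴) before the
  beta likelihood.
- Sampler determinism: every stochastic stage consumes an explicit integer
  seed; per-chain streams are derived offsets.

## Problem sizes used by the test suite and acceptance script

Enumeration-oracle checks cover all integer valencies 1–4 with NL, NR ≤ 3
(100 draws each, 3 600 cases); conservation runs 1 000 random equilibria;
prior round trips 1 000 pairs over 10⁴–10⁸ M⁻¹; the screen fit uses the
48-condition single-subclass screen × 3 replicates with the reduced 2 × 500
sampler preset; mixture validation scores all 288 held-out mixture
conditions; depletion recovery averages 20 independently seeded studies.

## Known limitations

- Affinity point identification is prior-dependent along the global
  `Ka·Kx*` ridge and for receptor-saturating interactions (above).
- Ensemble MCMC draws within a chain are correlated walker states;
  R-hat across independently seeded ensembles is the operative
  convergence check, and quantile estimates at the default presets are
  Monte-Carlo accurate to a few percent, not arbitrary precision.
- The beta observation model treats mice within a treatment as
  exchangeable; donor-level hierarchy is not modeled.
- FcγRIIIB alleles and IgG allotypes are representable (any affinity
  table works) but carry no dedicated machinery.
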