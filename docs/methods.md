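# Methods

This note documents the models, algorithms and numerical choices behind
`lj6p`, in enough detail to reproduce or audit any stage.

## Potential and units

The generalized Lennard-Jones 6-p pair potential is
`V(r) = 4ε[(σ/r)^p − (σ/r)^6]` with `ε > 0` (kcal/mol), `σ > 0` (Å) and
the repulsion exponent `p > 6` treated as a continuous real parameter;
`p = 12` recovers the classical form.  Working units are kcal/mol, Å, K
and atm, with `k_B = 0.0019872041 kcal/(mol·K)` as a package constant.
Truncation, where applied, is a hard set-to-zero beyond `r_c = 3σ` with no
energy shift; the discontinuity (order `4ε·3⁻⁶ ≈ 0.005ε`) is irrelevant
for curve fitting.  The analytic well minimum sits at
`r_min = (p/6)^{1/(p−6)} σ`; as `p → 6⁺` the minimum drifts to
`e^{1/6} σ` and the well depth vanishes, which is why small exponents
produce soft, shallow potentials.

## Forward models

**Dimer binding energy** `E(r)`: the untruncated potential evaluated on
the scan grid.  Untruncated because a quantum dimer scan resolves the
attractive tail beyond any simulation cutoff; imposing a hard zero there
would make the model curve unphysical precisely where the data are most
informative about `ε`.

**Dilute-gas RDF** `g(r) = exp(−V_trunc(r)/k_BT)`: the exact radial
distribution function in the low-density limit, used as the desk-scale
stand-in for an MD-computed liquid RDF.  It uses the *truncated* potential
to mirror the simulation convention (so `g ≡ 1` beyond `3σ`), and it
preserves the parameter sensitivities that drive the inference — `σ` sets
the peak location, `ε` its height — while evaluating in microseconds.  It
does **not** emulate the oscillatory second and third shells of a dense
liquid, nor any thermodynamic consistency between the `(T, P)` labels and
the curve; conclusions drawn from it concern the *pipeline* (samplers,
evidence, pooling), not liquid-state physics.  The exponent of the RDF is
clipped to ±50 before exponentiation so that deep-well proposals produce
finite, ordered likelihoods instead of overflow.

**External engines.**  Bulk observables (liquid RDFs, density, diffusion)
require a molecular-dynamics engine.  The package deliberately contains
none: `register_external_engine` wraps a command template with
`{epsilon} {sigma} {p} {temperature} {pressure}` placeholders, expects a
two-column r/value table on stdout, and converts missing executables,
crashes, parse failures and grid-length mismatches into typed engine
errors.  The documented reference protocol for such a backend (666 atoms,
periodic boundaries, NPT equilibration of 5×10⁶ × 2 fs steps, NVE
production of 10⁵ steps, RDF over 100 bins) lives entirely on the engine
side of the contract.

## Likelihood and priors

Each dataset contributes a Gaussian likelihood with i.i.d. per-bin noise,
`log L = −(N/2)·log(2π σ_n²) − SSE/(2σ_n²)`, with a single inferred noise
scale `σ_n` per dataset and no bin weighting; the RDF peak dominating the
sum of squared errors is an emergent property of the data, not a scheme.
`σ_n` is sampled on its natural scale against a uniform prior `[10⁻⁶, 1]`.

Base priors are wide uniform boxes:
`(ε, σ, σ_n) ∈ [0.05, 3] × [3, 4] × [10⁻⁶, 1]` for LJ 6-12 and
`(ε, σ, p, σ_n) ∈ [0.05, 10] × [3, 4] × [6.01, 15] × [10⁻⁶, 1]` for
LJ 6-p (the wider `ε` range accommodates the strong `ε`–`p` correlation:
softer repulsion demands larger `ε` for the same well).

Two conditional-prior families serve the hierarchical layer, both acting
on the physical parameters only and both renormalized over the base box so
they integrate to 1 for every admissible `ψ`:

* `independent_truncated_normal` (default): `ψ = (loc_i, scale_i)` per
  parameter; smooth shrinkage, large scales recover the uniform box.
* `uniform_box`: `ψ = (lo_i, hi_i)`, a movable sub-box.

The family choice is a configuration key and can itself be compared by
evidence.

## TMCMC

The sampler tempers `prior · likelihood^{p_j}` from `p_0 = 0` to
`p_J = 1`.  Stage control: the next exponent is the largest step for which
the coefficient of variation of the incremental weights
`exp(Δp (ℓ − max ℓ))` stays at the target (default 1.0).  CoV uses the
sample standard deviation (ddof = 1).  The step is found by bisection to
an absolute tolerance of 10⁻¹⁰; when the log-likelihood spread is so
extreme that the admissible step is smaller than that (stage 0 of an RDF
fit can see spreads of 10⁵⁰ because the clipped curves reach e⁵⁰ while
`σ_n` extends to 10⁻⁶), the search falls back to geometric descent with
relative refinement, so the schedule always makes strictly positive
progress and then accelerates geometrically.

The log-evidence accumulates as `Σ_j log mean_i w_ij` over stages — the
standard tempering estimator, computed in log space.

Within a stage: multinomial resampling by weight; each unique leader then
runs a Gaussian random-walk Metropolis–Hastings chain whose length equals
its resampling multiplicity, emitting every post-step state, so the
population size is constant.  Each emitted state takes `chain_steps`
(default 3) MH steps.  This chain-per-leader scheme, rather than one
independent step per resampled copy, is essential for sharply peaked
posteriors: with a single step the population provably lags the
contracting mode (on the dimer fixture the final population sat at
`σ_n ≈ 0.011` against a true posterior at 0.006, and 5–95% intervals
under-covered badly); with multiplicity-length chains and three steps per
state, TMCMC intervals match long-run affine-invariant MCMC references in
location and width.  The proposal covariance is `β²` times the weighted
sample covariance (`β = 0.2` default) with a 10⁻¹² diagonal jitter;
proposals leaving the prior box are rejected, which truncates the
posterior correctly without bias.

All randomness flows from one root seed through a single generator in a
fixed call order: identical seed and configuration give bit-identical
ensembles.  Likelihood calls within a chain sub-step are batched and
order-independent.

Summaries: the MPV is the sample maximizing `log prior + log likelihood`
(ties to the lowest index); quantiles are per-parameter empirical
quantiles with linear interpolation.  Ensembles persist as a CSV of
samples plus a JSON sidecar (evidence, exponent schedule, seed, config,
surrogate statistics) using shortest-repr floats, which round-trip
exactly.

## Hierarchical layer

Stage 1 calibrates each dataset independently under the base prior.
Stage 2 samples `p(ψ | all data)` with TMCMC over a uniform hyperprior
box — locations range over the base box, scales over
`(10⁻³·width, width)` per parameter — using the self-normalized
importance-sampling estimate

`log p(d_i | ψ) ≈ log Z_i + log( (1/N) Σ_k p(θ_ik | ψ) / p(θ_ik | base) )`,

which reuses the stage-1 draws instead of re-running the forward model per
`ψ`.  Stage 3 refreshes each dataset by resampling its stage-1 ensemble
with weights proportional to the prior ratio averaged over the *full*
`ψ` posterior (marginalizing `ψ`, not plugging in its MPV).  Exactly
uniform refresh weights short-circuit to the identity, so a hyperprior
concentrated on the base box reproduces the non-hierarchical result
bit-for-bit.  Effective sample sizes of every importance step are
recorded, with a warning below a configurable floor (default 50), so
estimator degeneracy is visible rather than silent.

`σ_n` stays outside the hierarchical tie: it is condition-specific
measurement/model error, and pooling it would let a noisy condition
corrupt the noise estimates of clean ones.

## Kriging surrogate

The surrogate operates on the scalar the sampler consumes — the
log-likelihood — not on raw curves.  For each chain leader, a box of
per-dimension width equal to a quarter of the current sampling domain
(read as the bounding box of the current stage's population, so it
tightens as the sampler concentrates) is centred on the leader and clipped
to the domain.  Training points are the truly evaluated points inside the
box, capped at the 32 nearest the leader so fits stay O(1).  The
interpolant is ordinary kriging: squared-exponential correlation in
box-scaled coordinates, one length-scale chosen by maximizing the
concentrated marginal likelihood over a fixed geometric grid
(0.05–2.0, 10 points), relative nugget 10⁻⁸, and the ordinary-kriging
standard error including the mean-estimation term.

A prediction replaces a true evaluation only if (i) the box holds at least
`2·dim + 1` training points, (ii) the kriging standard error is at most 5%
of |predicted value|, and (iii) the prediction lies inside the 5–95%
quantile band of all true objective values seen so far.  Singular
correlation matrices degrade to "too few points" — never an exception into
the sampler.  Every rejected or out-of-box query triggers exactly one true
evaluation (an accounting invariant asserted in the tests).  The 5% rule
is relative, so objectives near zero auto-reject — conservative by
construction.  On a multi-stage conjugate benchmark the surrogate answers
~95% of queries while shifting the evidence by ~10⁻³.

## Model selection and robust prediction

Bayes factors are `exp(E₂ − E₁)` from per-dataset non-hierarchical
log-evidences, with bookkeeping in log space.  Because TMCMC evidence
includes all prior-normalization constants, models of different
dimensionality compare directly, and the flexible 6-p model pays an
automatic Occam penalty when its extra exponent is superfluous.

Robust prediction evaluates a forward model at the ensemble MPV and at a
posterior subsample (default 100 draws, with replacement when the request
exceeds the ensemble) and reports the MPV curve with pointwise 5–95%
bands.  Individual draw failures are dropped and counted; beyond 50% the
prediction aborts.  Scalar prediction quality is the mean squared relative
error `(1/N) Σ ((g_k − r_k)/r_k)²` over conditions; RDF quality is the
mean over conditions of the per-curve mean squared error.  Density and
diffusion are accepted through the generic forward-model interface but
have no built-in implementation — they require an MD engine through the
adapter, a documented limitation.

## Synthetic data

Every fixture is a noiseless forward curve from a known truth plus
i.i.d. `N(0, σ_n²)` noise — exactly the likelihood's own noise model, so
recovery studies are well-posed and the fitted `σ_n` concentrates near the
generating value.  Grids: dimer scans span `0.9σ` to `2.5σ` over 40
points (repulsive wall, well, attractive tail); RDF curves span 2.5–12 Å
over 100 bins, the standard RDF discretization.

Preset ground truths re-use published posterior values for argon — the
gas-phase row (ε = 0.252, σ = 3.370, p = 12.703, σ_n = 0.006) and the six
liquid/vapor rows (p ≈ 6.3–6.6, σ ≈ 3.1–3.45) at their `(T, P)`
conditions — which anchors every fixture's magnitudes to the real
calibration problem without claiming to reproduce data-dependent
posteriors.  The model-selection fixtures use a classical-literature 6-12
truth (ε = 0.2824, σ = 3.3605) and a soft-repulsion truth
(ε = 0.30, σ = 3.40, p = 6.5); their shared noise scale 0.01 kcal/mol was
chosen once as the RMS residual of the best 6-12 fit to the noiseless
p = 6.5 curve, so model misfit and noise floor are comparable and the
selection question is genuinely contested.

What passing tests do and do not show: recovery, selection and pooling
results certify the *inference machinery* under the assumed noise model;
they say nothing about MD-scale liquid physics, which enters only through
the engine adapter.

## Study sizes

The shipped studies use: 2000 samples/stage for 3+1-parameter models and
4000 when `p` is inferred (their package defaults); 10 seeds for the
conjugate-evidence and model-selection studies; 20 seeds for dimer
exponent recovery; stage-1 1500 / hyper 800 samples for the hierarchical
pooling study; 500 samples/stage for the surrogate benchmark.  These sizes
give Monte-Carlo errors comfortably inside every tolerance they are
checked against while keeping each study in the seconds-to-a-minute range.

## Known limitations

* The dilute-gas RDF is exact only in the low-density limit; liquid
  structure beyond the first peak is not emulated.
* No built-in density/diffusion observables; both need an external engine.
* The hierarchical estimator inherits importance-sampling degeneracy when
  the hyper-posterior concentrates far from a dataset's stage-1 cloud; the
  recorded ESS is the diagnostic.
* Evidence estimates carry the usual tempering bias at small population
  sizes; nested-box consistency is verified to ~0.1 in log-evidence.
* Quantile coverage of TMCMC intervals matches the exact posterior's
  nominal rate, but the exact 5–95% interval itself misses the generating
  truth for ~10% of data realizations by construction.
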