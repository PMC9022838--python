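# Methods

This document describes the mathematical model, the assumptions baked
into the implementation, the main parameters and their defaults, the
numerical choices, and known limitations.

## 1. Network model and flux parameterization

A model is a list of reactions with atom-mapped metabolite terms
(`network_model`). Each metabolite carries a carbon count and a role
(internal, external substrate, or unbalanced dilution pool); reactions
map substrate carbon positions to product positions with lowercase
letters, and fractional stoichiometric coefficients are supported
(used for the symmetric-cleavage test network). Reversible reactions
are split into separate forward and `_rev` fluxes.

At metabolic steady state the internal metabolite balances give
`S v = 0`. The feasible flux space is parameterized through the
rational null space of `S` computed exactly (sympy reduced row echelon
form over rationals), giving `v = K u` with `u` the free fluxes. One
flux may be fixed (default: the substrate uptake normalized to 1),
which removes the overall scale and leaves `p = nullity − 1` free
parameters. Feasibility is `v ≥ 0` elementwise (all fluxes are net,
irreversibility handled by the split).

## 2. Labeling simulation (EMU cascade)

Measured MIDs are simulated with the elementary metabolite unit (EMU)
decomposition: starting from the full EMUs of the measured
metabolites, the dependency graph is traversed backwards and grouped
into size blocks. Each size-`n` block solves a linear system
`A_n(v) X_n = B_n(v) Y_n`, where `Y_n` stacks tracer inputs and
convolutions of smaller solved blocks. `A` and `B` are linear in `v`
and are assembled densely from precomputed sparse maps
(`vec(A) = M_A v`), then factorized once per block with LAPACK
`dgetrf`/`dgetrs`.

Analytic sensitivities `dX/du` reuse the same LU factors:
`A dX = (dB Y + B dY − dA X)` for each free-flux direction. These feed
the SSR gradient used by the optimizer and the profile machinery.

Assumptions: isotopic and metabolic steady state; well-mixed pools;
no natural-abundance correction inside the MFA simulator (synthetic
data is generated from the same convention); carbon-only labeling.
Zero fluxes make a block singular, so the solver floors fluxes at
1e-9 during fitting (strict mode, used for direct simulation, raises
instead).

## 3. Estimation

Measurements are records `(tracer, metabolite, mass_isotopomer, value,
sd, replicate, split)`. Replicates are aggregated before fitting:
values by mean, uncertainties as `mean(sd)/sqrt(n)` (standard error of
the mean); aggregation is idempotent.

The objective is the σ-weighted residual sum of squares
`SSR(u) = Σ ((m_i − ŷ_i(K u)) / σ_b,i)²`, minimized by multistart
SLSQP with the analytic gradient, subject to `K u ≥ 0` and the fixed
normalization row. Starts are drawn as Dirichlet combinations of the
feasible cone's linear-programming vertices, so every start is
feasible. Defaults: 20 starts (10 in the benchmark), `ftol` 1e-9,
`maxiter` 2000. Fits are deterministic given `(seed, n_starts)`.

Fitting the believed sigmas: weighted least squares is invariant under
a homogeneous rescaling `σ → cσ` — the minimizer is unchanged and the
SSR scales by exactly `1/c²`. The package exploits this both for
testing and for the benchmark (section 6).

## 4. Model selection

`score_models` fits each candidate to the estimation split and records
per-model: estimation SSR, χ² threshold `χ²_{α}(N − p)` with `N` the
number of aggregated estimation records and `p` the number of free
parameters, AIC `SSR + 2p`, BIC `SSR + p ln N`, and validation SSR
(prediction error on the held-out split with no refitting). Six
selection rules are provided:

- `ssr` — smallest estimation SSR (always favors the most flexible model);
- `first_chi2` — most parsimonious candidate passing the χ² test
  ("none" if all fail);
- `best_chi2` — largest margin `threshold − SSR`;
- `aic`, `bic` — smallest information criterion;
- `validation` — smallest validation SSR.

Near-ties (relative tolerance 1e-6, absolute 1e-9) are broken toward
fewer parameters, then lexicographic model id. This is a numerical
guard, not a tuning knob: nested supersets of the true model reach
floating-point-identical optima and would otherwise be selected by
optimizer noise.

## 5. Believed-sigma perturbation

The central stressor is the mismatch between the generating noise σ_r
and the believed σ_b used for weighting and testing. A σ_b *level* c
draws per-observation factors uniformly from `c × [0.8, 1.2]` (e.g.
level 0.1 → [0.08, 0.12]) and multiplies the recorded sds by them.
Shipped levels: 0.1, 0.3, 1, 3, 10.

## 6. Benchmarks

`run_benchmark` repeats, for each resample index `i`: regenerate data
with a counter-based seed (`SeedSequence([master, i])`), draw one set
of base factors from `U[0.8, 1.2]`, fit all candidates once, then
score each σ_b level by rescaling (`SSR/c²`, re-applied χ²/AIC/BIC).
Because every level's factor range is an exact multiple of the base
range, levels are compared on the same data and the same relative
sigma pattern — a controlled experiment in which only the overall
believed-sigma magnitude varies. A consequence worth knowing when
reading the output tables: the validation method's frequencies are
*exactly* equal across levels, which is the invariance the method is
designed to have.

Three families ship with scaled-down defaults (full-scale designs are
available via `full_scale=True` / `--full-scale`):

| family     | truth                     | candidates      | σ_r  | resamples (default/full) |
|------------|---------------------------|-----------------|------|--------------------------|
| polynomial | order-7 polynomial        | orders 1–14     | 0.2  | 1000 / 10000             |
| linear     | 3-parameter sparse map    | 1–6 parameters  | 5.0  | 200 / 1000               |
| mfa        | TCA model `m4`            | `m1`–`m7`       | 0.03 | 30 / 100                 |

A failed fit in a resample records a `"none"` selection rather than
aborting the study.

## 7. Uncertainty

**Prediction profile likelihood (PPL).** An interval for a scalar
prediction is obtained by stepping a target value away from the
best-fit prediction and re-optimizing the penalized objective
`SSR + W (pred − target)²` at each step; the endpoint is the last
target whose *unpenalized* SSR stays within `χ²_{α}(1)` of the
optimum. Defaults: `W = 1e6`, step 0.005 (MID scale) with optional
geometric growth for unbounded quantities (flux intervals use step
0.01, growth 2, cap 5). Caveat: the penalty weight must dominate the
curvature of the data term; for extremely sharp objectives (believed
sigmas orders of magnitude below the residual scale) `W` must be
raised or the profile will overshoot.

**Flux confidence intervals** apply the same machinery to
`v_j = (K u)_j` of the scale-fixed model.

**MCMC.** Metropolis–Hastings in the free fluxes with an isotropic
Gaussian proposal, scale adapted during a 10% burn-in toward a
0.2–0.4 acceptance rate; samples within `χ²_{α}(dof)` of the optimum
are retained and prediction intervals are taken as min–max (or
percentiles) of the retained set. Acceptance below 1% after
adaptation raises an error advising a proposal rescale.

**Novelty assessment.** A candidate validation experiment is
classified per measured fraction by its prediction interval: wider
than 0.9 → uninformative because unconstrained ("too novel"),
predictions within `2 σ_b` of existing estimation data → "too
similar", otherwise "informative". A fast surrogate compares the rank
of the stacked measured-MID sensitivity map with and without the
candidate tracer.

## 8. Lipid mixture model

Lysophosphatidylcholine-derived palmitate is modeled as a mixture of
pre-existing palmitate (natural-abundance MID, ¹³C fraction 0.0107)
and newly synthesized palmitate (8-fold convolution of the cytosolic
acetyl-CoA 3-entry MID), both convolved with the measured
glycerophosphocholine backbone MID. The mixing fraction α has a
closed-form weighted-least-squares solution, clipped to [0, 1] with a
flag; the estimator raises if the new and pre-existing spectra
coincide (α unidentifiable).

## 9. Known limitations

- Carbon-only tracers; no multi-element isotopomers and no
  natural-abundance correction matrix for measured fragments.
- Absolute fluxes are not identifiable from MIDs alone; all shipped
  problems fix the substrate uptake to 1 and report relative fluxes.
- Nested model families produce exactly tied fits; selection then
  relies on the documented parsimony tie-break rather than the data.
- The χ² test's degrees of freedom use `N − p` with `N` the number of
  aggregated records, which overstates dof slightly when records are
  correlated through the simplex constraint of each MID.
- PPL intervals are stepping-resolution limited (±1 step) and assume a
  unimodal profile; MCMC intervals inherit Monte-Carlo error and the
  min–max mode widens with sample count.
- The benchmark's believed-sigma levels share base factors by design;
  independent per-level draws would add sampling noise to cross-level
  comparisons but are not implemented.
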