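# Methods

## Model and procedure

A bulk tumor sample with tumor cell fraction (purity) `p` measures, at one
CpG, the mixture `beta = p·T + (1 − p)·N` of the tumor-compartment state
`T` and the aggregate microenvironment ("normal") state `N`, plus
measurement noise. Because somatic methylation changes usually affect only
a subset of tumors at a locus, a cohort can hold several latent sample
populations with different `T` but a shared `N`. Within a population the
observed beta is linear in `1 − p` with intercept `T` and slope `N − T`,
so the procedure per CpG is:

1. **Discovery.** Add N(0, 0.005²) noise to a working copy of the betas
   and fit mixtures of linear regressions of (noisy) beta on `1 − p` for
   K = 1, 2, 3 by EM, three restarts per K; select K by BIC. The noise
   exists solely to stop near-zero-variance populations (e.g. fully
   unmethylated samples) from attracting degenerate low-variance
   components; all later regressions use the original betas.
2. **Detrending.** For each discovered population, OLS of the original
   beta on `1 − p` gives the pure-tumor intercept; each sample's purified
   beta is that intercept plus its residual. The same regression against
   `p` gives the inferred-normal intercept and the per-sample inferred
   normal beta. The two parametrizations describe one line, so the two
   residual vectors are identical and (pre-clamp) normal − tumor equals
   the fitted slope within a population — both identities are asserted in
   the test suite at 1e-10.
3. **Clamping.** Values below 0 or above 1 are set to 0 and 1 after
   residual re-addition. Clamping is the only nonlinearity applied.

If model selection returns a single population, the whole cohort is
detrended as one group; this K = 1 path coincides with classical
single-compartment purity correction and with closed-form OLS detrending
(verified to 1e-8 against a polyfit oracle).

## EM details and numerical choices

* **Initialization**: random hard partition of samples into k balanced
  groups from the seeded generator, then one M-step. Restart seeds are
  derived from (seed, k, replicate) through numpy's `SeedSequence`
  hashing, so restarts are independent yet reproducible.
* **Convergence**: relative log-likelihood change below 1e-6, cap 200
  iterations. The log-likelihood trace is recorded and is non-decreasing
  between component drops (property-tested).
* **Component dropping**: components whose mixing weight falls below 0.05
  (the conventional minimum-prior default for mixture-of-regression
  fitting) are removed mid-EM and the weights renormalized, so a requested
  K = 3 fit can legitimately return fewer components.
* **Residual-SD floor**: 1e-4, preventing likelihood blow-up when a
  component captures a zero-variance set of samples.
* **BIC**: `−2 logL + p ln(n)` with `p = 3K + (K − 1)`; ties within 1e-9
  go to the smaller K.
* **Degenerate inputs**: a constant response yields slope 0 and K = 1; a
  zero-variance covariate is only identifiable at K = 1 and larger K are
  skipped during selection; populations with fewer than 3 members cannot
  support OLS and are merged into the population with the nearest
  intercept; missing betas are excluded from the fit and emitted missing.
* **Purity domain**: (0, 1]. Purity exactly 1 is valid (it contributes
  leverage at the tumor intercept); purity 0 is rejected — there is no
  tumor signal to recover.
* **Determinism**: every CpG's seed derives from (global seed, row index)
  only, so outputs are bit-identical for any worker count and independent
  of probe names; per-row failures are flagged in the fit summary and the
  row passes through unadjusted rather than aborting the matrix.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `noise_sd` | 0.005 | SD (beta units) of discovery-only noise |
| `k_max` | 3 | maximum populations per CpG |
| `nrep` | 3 | EM restarts per K |
| `min_weight` | 0.05 | component-drop threshold (mixing fraction) |
| `tol`, `max_iter` | 1e-6, 200 | EM stopping rule |
| output precision | 6 decimals | beta resolution far above array noise |

## Synthetic cohorts

The generator draws, per CpG, a population count K from a configurable
distribution, K tumor states from a set of allowed levels (pairwise
separation ≥ 0.2 when K > 1 — closer states are not resolvable as separate
regression lines at realistic noise), one shared normal state, a random
(optionally subtype-driven) population assignment per sample, and emits
`p·T + (1 − p)·N` plus Gaussian noise, clamped to [0, 1]. Purity defaults
to Uniform(0.2, 0.95), a wide bounded range that exercises the regression
geometry. Benchmark cohorts use 630 samples — a realistic consortium-scale
cohort — with 40-800 CpGs depending on the experiment; the recovery
benchmark uses tumor states {0, 0.5, 1}, normal states {0, 0.3, 0.7}, and
measurement noise SD 0.03.

What the generator does **not** emulate: probe-chemistry biases between
Infinium I/II designs, batch effects, spatially correlated CpGs, multiple
distinct cell types within the microenvironment (one aggregate normal
compartment only), or errors in the purity estimates themselves (those are
studied explicitly by the perturbation utilities). Passing recovery tests
therefore show that the estimator inverts the model it assumes, not that
real arrays satisfy that model.

One consequence of the [0, 1] clamp worth knowing: a "single-population"
CpG whose generating line sits at a boundary (tumor and normal both 0,
say) has about half its noise clamped, and genuinely is not one Gaussian
line — the mixture then (correctly) splits clamped from unclamped samples.
The model-selection benchmark therefore measures the K = 1 rate on
interior lines, where the single-Gaussian-line assumption actually holds;
detrending accuracy is unaffected either way because all populations of
such a CpG share the same state.

## Perturbation experiments

`perturb_purity` adds N(0, s²) to each purity and clips to [0.01, 1.0]
(out-of-range perturbed purities must stay valid; the clip bounds are this
package's choice). The cohort sweep uses s = 0.01..0.19 step 0.02, five
replicates per s, and tracks population-call concordance (Hungarian label
matching per CpG), per-sample correlation of adjusted betas against the
unperturbed run, inferred-normal correlation, and the mean adjustment
magnitude. The single-CpG sweep uses s = 0.02..0.50 step 0.02 on a
promoter-hypermethylation-like locus (a hypermethylated minority over a
low normal background, 235 samples). Whether an s = 0 point belongs at the
head of a grid is left to the caller — `noise_grid` emits exactly the
inclusive arithmetic sequence requested. As purity noise grows the fitted
slopes flatten toward zero, so the adjustment shifts betas *less*; the
decreasing mean-shift curve is expected behavior, not a defect.

## Evaluation choices

* Sample clustering: Pearson distance (1 − r) with Ward linkage, tree cut
  at K = 2. Ward on a correlation (non-Euclidean) distance has a known
  theoretical caveat but is the field's common practice for methylation
  subtyping and is used as such here. Constant sample profiles make
  Pearson undefined and are jittered by 1e-9 with a warning.
* Split metrics: the cluster-to-class mapping is the accuracy-maximizing
  one of the two possibilities (so accuracy ≥ 0.5 by construction); the
  positive class for sensitivity/specificity is a parameter.
* Dichotomization baseline: beta > 0.3, strictly.
* Trimodal binning: default cuts (0.25, 0.75) for the hypo / intermediate
  (X-inactivated) / hyper categories expected at X-chromosome promoters in
  females. The cuts are a documented assumption, configurable.

## Known limitations

* Inference is per-CpG and ignores spatial correlation along the genome.
* The normal compartment is a single aggregate state; cohorts with
  heterogeneous microenvironments violate this.
* Extrapolation to purity 0 and 1 inherits OLS leverage effects: cohorts
  with narrow purity ranges give unstable intercepts.
* Population discovery needs a reasonable number of samples per state;
  with fewer than ~10 samples the fit is refused, and small populations
  (< 3) are merged rather than modeled.
* Exact numerical parity with other mixture-of-regressions software is not
  promised — only behavioral parity on the geometry described above
  (their minimum-prior, iteration and degrees-of-freedom conventions
  differ in undocumented ways).
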