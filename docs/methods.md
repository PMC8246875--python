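# Methods

## Model

The generalized partial credit model (GPCM) describes the probability
that subject *n* (ability θₙ) responds in ordered category
*x* ∈ {0,…,mᵢ} of item *i* (thresholds βᵢ₁…βᵢₘᵢ, discrimination αᵢ > 0):
the cumulative logit of category *k* is s_nik = αᵢ (k·θₙ − Σ_{j≤k} βᵢⱼ),
and the category probabilities are the softmax of (s_ni0,…,s_nimᵢ) with
s_ni0 ≡ 0. Discriminations are carried internally as ln αᵢ, which keeps
αᵢ positive without constraints and makes their ridge penalty quadratic.
Missing responses simply drop out of the likelihood (complete-case per
cell); no missing-data mechanism is modelled, which is appropriate only
when missingness is ignorable.

## Estimation

Joint maximum likelihood over persons and items is non-identifiable
(location/scale) and diverges for perfect or zero scores. Both problems
are resolved by ridge penalties rather than explicit constraints:

    F_S(θ, β, α) = L_S(θ, β, α) − λθ Σₙ θₙ² − λα Σ_{i∈S} (ln αᵢ)².

Maximization uses L-BFGS-B on the full free parameter block with
analytic gradients in (θ, β, ln α); convergence when the projected
gradient inf-norm drops below 1e-5 or the relative objective change
below 1e-9, with an iteration cap of 500. A fit that stops at the cap is
flagged (`converged=False`), never silently accepted; this occurs
occasionally in excluded-set fits whose discriminations shrink towards
zero, where the likelihood surface is extremely flat and the reported
criterion value is insensitive to the remaining drift. Initialization:
abilities from standardized, centered raw sum scores (zero for subjects
with no observed response — their ability is then determined by the
penalty alone and they are reported); thresholds 0; ln α = 0. Warm
starts from a neighboring itemset's fit are used heavily by the search;
every fit still runs to the full tolerance, so warm starts change speed,
not (up to local-optimum effects of the non-convex joint problem)
results. An optional seeded multi-start (`n_restarts`) jitters the
initial point and keeps the best final objective.

The likelihood/gradient kernel is vectorized over all subject×item
cells and JIT-compiled with numba (a pure-numpy implementation of the
same math remains as fallback and as a cross-check in the tests).

## The IPOQ-LL criterion

For a split into included items S_in and excluded items S_out:

1. joint penalized fit on S_in with λθ = .05, λin = 50;
2. IQ-LL = unpenalized log likelihood of that fit on S_in;
3. with abilities frozen, penalized fit of the excluded items'
   (β, α) with λout = .05 and no ability penalty;
4. OQ-LL = unpenalized log likelihood of that fit on S_out;
5. IPOQ-LL = IQ-LL + OQ-LL.

Only unpenalized likelihoods enter the criterion; the penalized
objective values are retained in the fit results for inspection. The
asymmetry λin ≫ λout is essential: included items are forced towards
equal (Rasch-like) discriminations, while excluded items may shrink
their discrimination and thereby cap the cost of unpredictable
responses. With *equal and weak* penalties, moving an item from the
excluded to the included set never decreases IPOQ-LL (verified on small
instances); with strong equal penalties this can be violated by the
penalty's distortion of the refit, which is why the guarantee should be
read in the weak-regularization regime.

## Itemset search

Stepwise selection from the full survey: one backward-elimination step
(score all single-removals, keep the best), then up to two
forward-selection steps, each accepted only if the candidate strictly
improves the best score already recorded at that size by more than 1e-6
and does not revisit an itemset. The improvement threshold and the
visited-set guard prevent remove/re-add cycles driven by optimizer
noise. The exact interleaving of forward steps is a design choice of
this package; it reproduces the qualitative trajectory behavior
(occasional re-introduction of a too-greedily removed item) that
motivates stepwise over plain backward elimination. Ties are broken
towards the lowest item index, which together with deterministic fits
makes trajectories reproducible bit-for-bit, serially or in parallel
(joblib; candidates are scored independently and reduced in a fixed
order). The recommended instrument is the IPOQ-LL maximum over the
trajectory, but the best itemset of every visited size is recorded so an
instrument length can be fixed a priori. Exhaustive enumeration
(optionally at fixed size) is provided for P ≤ 20; the greedy trajectory
is bounded by it up to optimizer slack, with equality on most small
instances (checked in the tests, gap reported, not hidden).

## Diagnostics

Standard polytomous Rasch statistics, computed at the fitted GPCM
parameters (α̂ as fitted, not forced to 1):

* outfit_i = (1/Nᵢ) Σₙ z²ₙᵢ and infit_i = Σₙ (xₙᵢ−Eₙᵢ)² / Σₙ Wₙᵢ with
  z = (x−E)/√W, E and W the model mean/variance of a response
  (Wright–Masters mean squares). Items whose observed responses are
  constant still get computed values (the statistics are well defined
  whenever W > 0) plus a warning; NaN is reserved for genuinely
  undefined cases.
* residual correlations: pairwise Pearson correlations of the
  standardized residuals across subjects (pairwise-complete). Because
  the aggregation used in comparable reports is ambiguous, both the mean
  of absolute off-diagonal values and the signed mean are reported; the
  "no correlation > .3" screening flag uses the maximum absolute value.
* ability standard errors: se_n = 1/√I_n with test information
  I_n = Σ_{i∈S_in} αᵢ² Wₙᵢ over observed cells — unpenalized information
  at the penalized estimate (shrinkage moves the point estimate; the
  reported precision is that of the likelihood).
* person separation reliability PSR = (Var(θ̂) − mean(se²)) / Var(θ̂),
  clipped to [0,1]; sample variance with ddof=1.
* random-instrument baselines: seeded uniform size-k itemsets, each
  scored and diagnosed, yielding empirical reference distributions and
  the percentile of any reference instrument.
* chance overlap of two instruments: exact hypergeometric tail
  P(|A∩B| ≥ k).

## Simulated designs

The generators produce the package's validation conditions: 301
subjects, 6-item subsets, 2- or 5-category responses, drawn
independently from the GPCM (NumPy PCG64, pure functions of their seed).

* **inhomogeneous** (18 items, one dimension): discrimination blocks
  {.04,…,.065}, {.2,…,.45}, {2.6,…,2.85} — noise / intermediate /
  highly predictive subsets; abilities on the even grid −3(.02)3.
* **multidimensional** (18 items, three dimensions): the ability grid
  for subset 1 and independent permutations of it for subsets 2 and 3
  (same marginal, mutually decorrelated); all α = 1.
* **correlated** (12 items, two dimensions, polytomous): bivariate
  normal ability pairs at target correlation ρ, mapped affinely onto
  [−4, 4] (affine maps preserve Pearson correlation), redrawn until the
  empirical correlation is within ±.02 of ρ.

Unstated design constants were fixed once as field defaults: thresholds
evenly spaced and centered (dichotomous β = 0; 5-category
β = (−1.5, −.5, .5, 1.5)), multidimensional α = 1. Under these choices
the searches behave as intended: the inhomogeneous peak sits at the six
high-α items, the multidimensional optimum is one complete subset, and
the correlated design separates cleanly at ρ ≤ .3 while mixing emerges
at ρ = .4 and dominates from ρ = .5 — the peak size can fluctuate by a
seed's luck, which is why peak-location checks use the mode over five
seeds. What these simulations do *not* emulate: missing data,
differential item functioning, disordered thresholds, non-normal /
clustered ability distributions, or respondent styles; passing them
shows the selection mechanics work, not that any real survey meets the
model's assumptions.

## Numerical choices and limitations

* Category probabilities via max-subtracted softmax; stable for
  |α(θ−β)| up to overflow scale.
* Loaded data must use every category 0…mᵢ of every item at least once;
  violations are rejected with a pointer to the recode utility rather
  than silently collapsed.
* The joint likelihood is non-convex; single-start fits can land in
  local optima. The search re-polishes every candidate to full
  tolerance, and scores of identical itemsets reached along different
  warm-start paths can differ by ~1e-2 — comparisons in the tests use
  tolerances of that order.
* Sub-minute searches hold for surveys of the validation scale
  (≈ 300 × 18, 5 categories, one core); cost grows roughly quadratically
  in the item count.
* Out of scope: CFA-based unidimensionality indices, DIF detection,
  multidimensional-ability GPCM, missing-data models, and alternatives
  to joint estimation (marginal/conditional ML).
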