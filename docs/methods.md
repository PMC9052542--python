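# Methods

## Model

For subject *i* with repertoire *R_i*, covariates
`X_i = [1, X_i1, …, X_iq]'` and trait *y_i*, the package assumes

```
E(y_i) = π( β'X_i + η'W'f(R_i) + h(R_i) ),   [h(R_1) … h(R_n)]' ~ N(0, τ²S)
```

with `π` the identity link for continuous traits and the logistic
function for binary traits. `f(R_i)` is the 20-vector of amino-acid
proportions in the repertoire, abundance-weighted: a sequence with clone
count *w* contributes *w* copies of each of its residues, and the count
vector is normalized to sum to one. `W` (20 × r, r < 20) maps the
composition onto r biochemical property scores. The global null "the
repertoire is unrelated to the trait" is `η = 0` and `τ² = 0` jointly.

## Fixed-effect score test

Under `H₀: η = 0, τ² = 0` the score for η is
`U_η = Σ_i W'f(R_i)(y_i − μ̃_i)` with `μ̃` the confounder-only null fit
(OLS for continuous traits; logistic IRLS for binary). Its covariance is
`Σ̃ = G'Γ̃G` with `G` the n × r matrix of weighted features and
`Γ̃ = Ω̃ − Ω̃X(X'Ω̃X)⁻¹X'Ω̃`, where `Ω̃` is diagonal with entries
`(1/n)Σ(y_i − μ̃_i)²` (continuous; the maximum-likelihood variance,
denominator n) or `μ̃_i(1 − μ̃_i)` (binary). `Γ̃` annihilates X, which
removes the nuisance-fit uncertainty from the score covariance.
`U_η'Σ̃⁻¹U_η` is referred to χ² with r degrees of freedom. The linear
solve is guarded: if the smallest eigenvalue of `Σ̃` falls below
`max(λ_max, 1)/1e12` (a constant or collinear feature) the test raises
rather than returning an unstable statistic.

## Repertoire-homology kernel

Pairwise sequence homology: `d(a, b)` is the optimal global
(Needleman–Wunsch) alignment score under BLOSUM62 or PAM250 with affine
gap cost `gap_open + gap_extend·(L − 1)` per gap of length L. Defaults
are `gap_open = 10`, `gap_extend = 0.5` — the EMBOSS `needle` defaults
for protein alignment — and are configurable. The normalized homology is

```
s(a, b) = d(a, b) / sqrt(d(a, a) · d(b, b))
```

so `s(a, a) = 1`; `s` can be negative for dissimilar pairs and negative
values are deliberately retained (flooring at zero would discard the
information that two sequences are *worse* than unrelated under the
substitution model).

Repertoire-level homology is an abundance-weighted best-match average:

```
S_ij = [ Σ_k w_ik·max_l s(a_ik, a_jl) + Σ_l w_jl·max_k s(a_ik, a_jl) ]
       / ( Σ_k w_ik + Σ_l w_jl )
```

The joint normalization by the combined clone count is the unique affine
normalization under which the kernel is exactly symmetric and has a unit
diagonal for arbitrary abundances (within a subject every sequence's
best match is itself with s = 1, so the numerator collapses to the total
clone count). The diagonal is therefore set to 1 analytically, avoiding
m² self-alignments per subject. Ties in the best match are harmless
because only the maximal value enters the sum. Inside `build_kernel`
each distinct sequence pair in the cohort is aligned once and reused
across subject pairs; the backend is Biopython's `PairwiseAligner`
(global mode), which the test suite pins against an exhaustive
enumeration of all alignment paths on short sequences under both
matrices.

`S` built this way need not be positive semi-definite. `psd_project`
eigendecomposes `S`, zeroes negative eigenvalues, and reconstructs from
the non-negative spectrum, recording how many eigenvalues were clipped
and the most negative one. Inputs already PSD (minimum eigenvalue
≥ −1e-10) are returned unchanged, making the projection idempotent.
Small positive eigenvalues are kept; only negatives are clipped.

## Variance-component score test

Testing `τ² = 0` with the score for τ² evaluated under the *joint* null
would require the covariance between the two scores, which is awkward
because `f(R_i)` and `h(R_i)` are correlated. Instead the kernel test is
run under `H₀′: τ² = 0` with η unconstrained: the null design is
`Z = [X | G]` (dimension d = q + 1 + r). For continuous traits,

```
U = (y − μ̂)'S(y − μ̂),   Q = (U − tr(SP₀)σ̂²) / sqrt(2σ̂⁴[tr(SP₀SP₀) − tr(SP₀)²/(n−d)])
```

with `P₀ = I − Z(Z'Z)⁻¹Z'` and `σ̂² = RSS/(n − d)`; Q is asymptotically
N(0, 1) under H₀′. For binary traits the logistic fit is linearized via
its IRLS working response: with weights `ω_i = μ̂_i(1 − μ̂_i)`, weighted
design `Z† = Ω̂^{1/2}Z` and weighted working residual
`(y − μ̂)/sqrt(ω)`, the same construction applies with daggered
quantities. Evaluating the kernel score at the H₀′ fit makes it
independent of the fixed-effect score, which is what licenses the Fisher
combination.

The p-value for Q is **one-sided (upper tail) by default**: τ² ≥ 0, so
only inflation of U above its null mean is evidence against H₀′. A
two-sided option is exposed (`two_sided=True` / `--two-sided`) since the
asymptotic normality statement itself does not fix the sidedness.

Degenerate case: for `S = I` (or any kernel aligned with the projection
null space) both the numerator and the variance of Q vanish identically
— the kernel carries no τ² information — and the test returns Q = 0,
p = 0.5 exactly. A vanishing variance with a non-zero numerator is an
error.

Comparison modes: `mode="fixed"` tests only η (the "extracted features"
strategy); `mode="random"` tests only τ² with the confounder-only null
design Z = X (the "sequence kernel" strategy, available under either
substitution matrix); `mode="combined"` runs both and combines
`−2(ln p_η + ln p_{τ²}) ~ χ²_4`. A p-value of exactly 0 (numerically
underflowed) is clamped to the smallest positive float with a warning
before taking logs.

## Numerical choices

* Logistic IRLS: convergence when the relative log-likelihood change is
  below 1e-10, at most 100 iterations; non-convergence (separation)
  raises a diagnostic error. Fitted probabilities are clamped to
  [1e-10, 1 − 1e-10] so the working response and weights stay finite.
* Continuous H₀ fit uses the MLE variance (denominator n) in `Ω̃`, the
  H₀′ fit uses the unbiased `σ̂²` (denominator n − d); both follow the
  definitions of the respective statistics.
* `tr(SP₀SP₀)` is computed as `Σ (SP₀) ∘ (SP₀)'` without forming the
  four-matrix product.
* Kernel export is plain TSV with subject IDs plus a JSON sidecar
  (matrix name, gap penalties, eigen-repair report) so a cached kernel
  is self-describing.

## Simulator

The generator emulates β-chain CDR3 repertoires at the level needed to
exercise the tests, not a biophysical V(D)J model:

* Sequence = head (4 aa) + middle + tail (2 aa). Heads CASS/CASR/CSAR/CAST
  with probabilities 0.7/0.1/0.1/0.1; tails YF/FF/HF/TF with
  0.4/0.4/0.1/0.1; middle of 4–10 residues uniform over the 20 amino
  acids; then 0, 1, or 2 extra residues inserted into the middle
  (mimicking P/N-addition diversity). Lengths span 10–18. The insertion
  law is not fully pinned down by the scheme, so the maximum-entropy
  choice is used: count uniform on {0, 1, 2}, residues uniform over the
  alphabet, positions uniform within the middle.
* Per subject: number of unique sequences uniform on {2, …, 25}
  (duplicates redrawn), clone abundances uniform on {1, …, 5}.
* Confounders `X1 ~ Bernoulli(0.5)`, `X2 ~ N(0, 1)`;
  `β = (0.1, 0.5, −0.4)`.
* Traits: linear predictor `β'X` plus, per scenario, `η·(W'f(R_i))`
  and/or `h ~ N(0, τ²S)` drawn through the eigen factor of the cohort's
  own (PSD-projected) kernel. Continuous traits add N(0, 1) noise;
  binary traits are Bernoulli draws, with the outcome vector alone
  redrawn (design, repertoires, and h held fixed) until each class holds
  at least 10% of subjects — the constraint is on the realized outcome,
  so redrawing y keeps the design comparable across replicates. Default
  effect sizes per scenario: fixed-only η = 1.6 (binary) / 0.8
  (continuous); random-only τ² = 8 / 0.8; both η = 1, τ² = 6 (binary)
  and η = 0.5, τ² = 0.6 (continuous).

What the generator does **not** emulate: V/J gene usage structure,
nucleotide-level recombination, sequencing error, clone-size power laws,
or shared public clones beyond what the common head/tail segments
induce. Passing simulation tests therefore demonstrate statistical
correctness of the tests under a plausible repertoire law, not
robustness to every feature of real AIRR-seq data.

`run_study` regenerates repertoires, covariates, and kernels each
replicate by default (`fixed_cohort=False`). The fixed-cohort mode draws
the cohort and kernels once and redraws only traits; it is an
approximation that removes cohort-level variability from the Monte-Carlo
error and exists because kernel construction dominates the cost
(O(n²m²) alignments). Rejection rates are always reported with binomial
standard errors so scaled runs remain interpretable.

## Study sizes used by the shipped checks

The packaged acceptance checks run the null calibration at n = 200 with
2,000 replicates (binary trait) and the power-ordering comparison at
n = 150 with 300 replicates (continuous trait), both in fixed-cohort
mode. These sizes keep a full run at a few minutes on one CPU while
leaving the binomial tolerances tight enough to detect miscalibration;
power levels at these sizes are naturally lower than at cohort sizes in
the hundreds, so the checks assert orderings and calibration bands
rather than absolute power values.

## Known limitations

* The model tests association only; with no explicit features behind
  the random effect, effect sizes are not estimable and the fitted
  object cannot predict outcomes.
* Survival phenotypes must be dichotomized; no censoring-aware (Cox)
  variant is provided.
* The kernel is O(n²) in subjects and O(m_i·m_j) alignments per pair;
  cohorts in the thousands will want the cached-kernel workflow.
* Alternative sequence distances (e.g. TCRdist) can conceptually replace
  `d(·,·)`, but only substitution-matrix alignment scoring is
  implemented.
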