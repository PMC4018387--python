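# Methods

## Problem setting and model

The package targets two-class classification from S named feature sources
(modalities) where missingness is *block-wise*: a subject either has all
features of a source or none. Subjects are grouped by availability pattern
into tasks; task i has nᵢ₁ positive and nᵢ₂ negative subjects over pᵢ
features (the union of its pattern's source columns). Tasks are numbered
deterministically: descending number of sources, ties broken
lexicographically on sorted source names. Subjects whose pattern has fewer
than `min_per_class` (default 2) subjects in either class are dropped —
the pooled covariance needs at least one centered vector per class, and
2 avoids accidental all-zero covariance rows.

Each class within each task is modeled as i.i.d. Gaussian with common
covariance. The classical rule classifies by sign((x − μ̂)ᵀ Σ⁻¹ δ); in high
dimension Σ̂ is singular, so the discriminant direction β = Σ⁻¹δ is
estimated directly by constrained ℓ₁ minimization:

    min ‖β‖₁  s.t.  ‖Σ̂β − δ̂‖∞ ≤ λ.

Statistics use the maximum-likelihood pooled covariance (divisor n = n₁+n₂
rather than n−2); the choice only rescales the natural range of λ and is
the convention of the constrained-ℓ₁ discriminant literature. Features are
not standardized by default; z-scoring is a caller decision, not applied
implicitly.

The multi-task program couples tasks through shared features. Because
(Σ̂ᵢβᵢ)ₖ estimates the population mean difference of feature k, agreement
across tasks is encouraged with an ℓ₁ penalty:

    min Σᵢ ‖βᵢ‖₁ + γ Σ_{(i,j): S_ij≠∅} Σ_{k∈S_ij} |(Σ̂ᵢβᵢ)ₖ − (Σ̂ⱼβⱼ)ₖ|
    s.t. ‖Σ̂ᵢβᵢ − δ̂ᵢ‖∞ ≤ λᵢ ∀i.

Design choices that were genuinely open:

* **Penalty, not hard constraint.** A penalty with weight γ reduces exactly
  to independent single-task fits at γ = 0; a hard bound of zero would
  instead force equality, the opposite limit.
* **ℓ₁ over ℓ∞ on the linking term.** The per-feature (ℓ₁) form treats each
  shared feature's disagreement separately, matching the feature-wise
  interpretation of the coupling; an ℓ∞ variant (one slack bounding the
  worst disagreement per task pair) is available via `link_norm="linf"`.
* **Pairwise linking** over all task pairs with nonempty shared sets; the
  canonical two-source instance has a single pair.
* **γ default = 1 / maxᵢ pᵢ**, scaling the linking term to be comparable to
  the ℓ₁ objective across dimensions. It is deliberately mild; tuning γ on
  a grid (`gamma_values`) is supported and is what the evaluation protocol
  uses when the linking strength matters.

Both programs are linearized in the standard way (β = β⁺ − β⁻ ≥ 0, one
nonnegative slack per linked shared feature; 2pᵢ fidelity rows per task)
and solved exactly with HiGHS through `scipy.optimize.linprog`
(primal/dual tolerance 1e-8). LP solutions can be degenerate: tests and
invariants compare objectives and constraint residuals, never raw β̂
equality, except where uniqueness is forced (identity-covariance cases).
Post-hoc fidelity checks allow 1e-6 constraint slack. An infeasible LP
(possible when Σ̂ is singular and λ too small) raises a signal that
parameter tuning treats as "invalid candidate".

Classification routes a subject to the task matching its availability
pattern and thresholds (x − μ̂ᵢ)ᵀβ̂ᵢ at 0. A score of exactly 0 goes to the
negative class — conservative toward the (typically larger) negative class
and fixed by contract. No class-prior term is added. A pattern with no
fitted task is an error rather than silently falling back to a sub-pattern
model.

## Feature screening

Before fitting, each task's features pass a univariate two-sample t-test
(classic pooled-variance, df = n₁+n₂−2; Welch behind `variant="welch"`).
The keep rules are asymmetric: task 1 (the richer pattern) keeps feature j
iff its own p-value p¹ⱼ ≤ τ; task 2 keeps a shared feature iff p¹ⱼ ≤ τ *or*
p²ⱼ ≤ τ — removal requires both screenings to fail, keeping more features
for the source-poorer task whose missing sources are correlated with the
retained ones. Ties at p = τ are kept (≤). For more than two tasks the rule
generalizes as: a feature survives in task i if it passes task i's own
screening or that of any task with strictly more sources; for two tasks
this reduces exactly to the asymmetric rules above. τ defaults to 0.01.
Degenerate inputs (both samples constant): equal means → (t, p) = (0, 1);
unequal → (±∞, 0) with a warning. Screening always uses training subjects
only and is recomputed inside every outer and inner CV split.

## Evaluation protocol

Outer k-fold CV is stratified independently within every task × class
stratum (fold sizes within a stratum differ by at most one; a stratum
smaller than k is an error). Inside each outer training set, an inner
5-fold CV (same stratification) selects the tuning parameters by mean
inner accuracy — accuracy because it is the headline metric; ties break
toward the smallest λs (sparsest model), then the smallest γ. Candidate
grids are log-equispaced with inclusive endpoints: the conventional ranges
are 20 points in [0.01, 1] for the single-task λ and 20 points per task in
[0.01, 10] for the multi-task λs, searched as a full product — faithful but
expensive, so the grid objects accept any size and the worked examples use
coarser ladders. The whole procedure is repeated (default 30 times), each
repetition re-randomizing both outer folds and inner splits from seed
`base_seed + r`; means and sample standard deviations are reported overall
and per task. Metrics: accuracy (TP+TN)/n, sensitivity TP/(TP+FN) — the
positive-class recall, specificity TN/(TN+FP); a zero denominator yields an
explicit undefined marker (`None`), never NaN arithmetic.

The three standard comparison arms are expressible through configuration
alone: the multi-task fit on all data; the single-task fit on one source
for all subjects (`restrict_sources`); and the complete-case single-task
fit (`complete_cases`).

## Synthetic generator and what it does (not) show

`SimConfig` draws each class from N(μ_c, Σ) over the full feature space and
blanks absent blocks per availability pattern, so observed features of all
subjects are marginally consistent with one joint model. Cross-block
dependence uses matched latent factors: feature k of block 1 and feature k
of block 2 correlate at ρ, making ρ directly the canonical correlation
between blocks (the diagnostic `canonical_correlation_diagnostic` recovers
it). Defaults: two blocks of 10 features, ρ = 0.8, a sparse mean shift of
0.5 on 5 block-1 features, and the canonical pattern counts 76/126
(both blocks) and 91/100 (block 1 only); `paper_scale_config` provides the
full 93+93-feature shape for slower runs. The Bayes oracle Φ(√(δᵀΣ⁻¹δ)/2)
assumes equal class priors and the common covariance; the generator itself
permits unequal counts.

What passing tests on these data do **not** show: robustness to
non-Gaussian marginals, heteroscedastic classes, nonlinear class
boundaries, or missingness that is informative (here blocks are missing
completely at random by design). Only the statistical skeleton of a
multi-modal ROI study — correlated blocks, block missingness, sparse mean
shift — is emulated.

## Study conditions of the built-in experiments

* **Bayes consistency**: complete single-source data, p = 10 (5 active
  features, shift 0.9, Σ = I, Bayes ≈ 0.843), 500 training subjects per
  class, λ selected on a 125-per-class validation split from
  {0.05, 0.1, 0.2, 0.4}, accuracy measured on 1000 test subjects per class,
  averaged over 10 seeds.
* **Multi-task benefit**: ρ = 0.8, blocks of 10 features, shift 0.35 on 5
  block-1 features; the complete-pattern task is starved (40 subjects per
  class) while the single-block task has 200 per class. Both arms tune on
  an identical 200-per-class complete-pattern validation draw — the
  baseline its λ, the joint fit its (λ₁, λ₂) product and
  γ ∈ {0, 0.5, 2, 10, 50} — and are compared on the same 200-per-class test
  draw, over 30 repetitions. Because task 2's large sample pins down the
  shared-feature mean differences, a nonzero γ transfers that information
  into the task-1 discriminant; the γ = 0 candidate keeps the joint arm's
  candidate set a superset of the baseline's.

These sizes keep the full suite and the acceptance script in the
seconds-to-minutes range while leaving the estimation problems genuinely
noisy.

## Known limitations

* The direct joint LP handles any number of tasks correctly but is not
  engineered for many sources: with S sources the pattern lattice and the
  pairwise linking blocks grow combinatorially, and decomposition methods
  would be needed at scale.
* λ grids products over many tasks explode combinatorially; per-task
  independent selection is sound only at γ = 0.
* Screening is univariate and ignores feature correlation; a correlated
  pair of which only one member carries signal may both be kept or both
  dropped.
* The reader enforces block consistency strictly; genuinely itemwise
  missing data require imputation upstream (out of scope here).
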