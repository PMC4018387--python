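# mlpd — multi-task linear programming discriminant analysis

Sparse linear discriminant classification for two-class studies that pool
several feature *sources* (modalities) when entire source blocks are missing
for many subjects — the situation of multi-modal neuroimaging cohorts where,
for example, every subject has an MRI ROI panel but only half also have PET.

Instead of discarding incomplete subjects or imputing whole blocks, the
dataset is decomposed into **tasks**, one per combination of observed
sources, and one linear classifier is fitted per task — jointly.

## The model

Within each task *i* with class matrices X₁, X₂ the package computes the
pooled statistics δ̂ᵢ = μ̂ᵢ₁ − μ̂ᵢ₂ and Σ̂ᵢ (maximum-likelihood pooled
covariance). The single-task **linear programming discriminant (LPD)**
estimates the Fisher direction βᵢ = Σᵢ⁻¹δᵢ without inverting Σ̂ᵢ, via a
Dantzig-type constrained ℓ₁ program:

    min ‖β‖₁   s.t.   ‖Σ̂ᵢ β − δ̂ᵢ‖∞ ≤ λᵢ

A new subject x is assigned to the positive class iff (x − μ̂ᵢ)ᵀβ̂ᵢ > 0,
with μ̂ᵢ the midpoint of the class means.

The **multi-task** program (MLPD) couples the tasks: (Σ̂ᵢβᵢ)ₖ estimates the
population mean difference of feature k, so for features shared by tasks i
and j the estimates should agree. The joint fit solves

    min Σᵢ ‖βᵢ‖₁ + γ Σ_{(i,j)} Σ_{k ∈ S_ij} |(Σ̂ᵢβᵢ)ₖ − (Σ̂ⱼβⱼ)ₖ|
    s.t. ‖Σ̂ᵢβᵢ − δ̂ᵢ‖∞ ≤ λᵢ   for every task i,

where S_ij is the shared-feature set and γ ≥ 0 controls how strongly the
tasks are tied together (γ = 0 decouples into independent LPD fits). Both
programs are plain LPs (solved with HiGHS via `scipy.optimize.linprog`), so
fits are exact and fast. Each task may keep a *different* subset of the
shared features — the flexibility that distinguishes this approach from
common-support multi-task feature learning.

Around the core the package provides two-sample t-test feature screening
with asymmetric keep rules (a source-poorer task keeps a shared feature if
it passes its own screening *or* that of a richer task), nested
cross-validation with per-task×class stratified folds and inner 5-fold
parameter selection, the accuracy/sensitivity/specificity report, and a
synthetic generator for correlated-block Gaussian data with block-wise
missingness, including the closed-form Bayes accuracy as an oracle.

## Worked example

```python
import numpy as np
from mlpd import (two_block_config, simulate_dataset, decompose_tasks,
                  repeated_cv_experiment, bayes_accuracy)
from mlpd.tuning import ParamGrid

# two correlated 6-feature blocks; 76/126 subjects with both, 91/100 with one
cfg = two_block_config(p_block=6, rho=0.8, effect=0.5, seed=0)
ds = simulate_dataset(cfg)
for t in decompose_tasks(ds):
    print(f"task {t.task_id}: sources={sorted(t.pattern)} n+={t.n1} n-={t.n2} p={t.p}")
print("Bayes accuracy of the generating model:", round(bayes_accuracy(cfg), 4))

grid = ParamGrid(values=np.geomspace(0.05, 0.5, 3), lo=0.05, hi=0.5, n=3)
summary = repeated_cv_experiment(ds, 5, "mlpd", reps=3, base_seed=0,
                                 tau=0.05, lambda_grids=grid,
                                 gamma_values=(0.0, 1.0, 5.0), inner_k=3)
for m, v in summary["overall"].items():
    print(f"{m}: {v['mean']:.4f} (sd {v['sd']:.4f})")
```

prints

```
task 1: sources=['MRI', 'PET'] n+=76 n-=126 p=12
task 2: sources=['MRI'] n+=91 n-=100 p=6
Bayes accuracy of the generating model: 0.8243
accuracy: 0.6658 (sd 0.0064)
sensitivity: 0.6287 (sd 0.0104)
specificity: 0.6932 (sd 0.0142)
```

The two availability patterns become two tasks sharing the six MRI
features. Mean 5-fold CV accuracy over three repetitions is 0.67 against a
Bayes ceiling of 0.82 — the gap reflects the modest per-task sample sizes,
the screening step, and the small tuning grid used here. Every stage
(screening, parameter selection) runs inside each training split only.

A `mlpd` console script exposes the same pipeline from the shell
(`mlpd simulate | fit | evaluate | cv`); real data enter as a CSV plus a
YAML schema mapping source names to column lists, with whole-block
missingness encoded as empty cells.

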