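"""Evaluation protocol: stratified CV, nested parameter selection, metrics.

The protocol mirrors standard practice for this family of classifiers:

* outer k-fold CV stratified *within every task x class stratum*, so each
  availability pattern contributes proportionally to every fold;
* inside each outer training set, feature screening is recomputed and an
  inner 5-fold CV picks the tuning parameters (lambda per task, optionally
  the linking weight gamma) by mean inner accuracy, ties resolved toward
  the sparser model (smallest lambdas, then smallest gamma);
* the whole procedure is repeated with fresh fold randomizations and the
  per-metric mean and standard deviation across repetitions are reported.

Test subjects never influence screening p-values or parameter choices: both
are recomputed from the outer training subjects of each fold.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .datamodel import (
    MultiSourceDataset,
    complete_cases,
    decompose_tasks,
    read_feature_table,
    read_schema,
    restrict_sources,
    shared_feature_set,
    write_feature_table,
    write_schema,
)
from .errors import LPInfeasibleError, MLPDError, PatternMismatchError, ScreeningEmptyError
from .joint import MLPDModel, default_gamma, fit_mlpd
from .screening import screen_tasks
from .slpd import fit_slpd, pooled_stats

__all__ = [
    "ParamGrid",
    "FoldAssignment",
    "MetricSet",
    "make_log_grid",
    "stratified_folds",
    "compute_metrics",
    "metrics_from_predictions",
    "fit_pipeline",
    "PipelineModel",
    "inner_cv_select",
    "cross_validate",
    "repeated_cv_experiment",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------


@dataclass
class ParamGrid:
    """Log-equispaced grid of candidate tuning values (endpoints inclusive)."""

    values: np.ndarray
    lo: float
    hi: float
    n: int

    def __iter__(self):
        return iter(self.values.tolist())

    def __len__(self):
        return self.n


def make_log_grid(lo: float, hi: float, n: int) -> ParamGrid:
    """n values with constant ratio ``(hi/lo)^(1/(n-1))``, first=lo, last=hi."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if n < 2:
        raise ValueError("need n >= 2")
    return ParamGrid(values=np.geomspace(lo, hi, n), lo=lo, hi=hi, n=n)


# ---------------------------------------------------------------------------
# Fold assignment
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    k: int
    assignment: dict  # subject_id -> fold id in [0, k)
    seed: int

    def test_ids(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_ids(self, fold: int) -> list:
        return [s for s, f in self.assignment.items() if f != fold]


def stratified_folds(tasks, k: int, seed: int) -> FoldAssignment:
    """Independent near-equal partition within each task x class stratum.

    Within a stratum of size n the fold sizes are ``ceil(n/k)`` for the
    first ``n mod k`` folds and ``floor(n/k)`` for the rest, so sizes differ
    by at most one.  Deterministic for a given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for t in tasks:
        for ids in (t.ids1, t.ids2):
            if len(ids) < k:
                raise MLPDError(
                    f"stratum of task {t.task_id} has {len(ids)} subjects < k={k}; "
                    "use a smaller k"
                )
            order = rng.permutation(len(ids))
            for pos, idx in enumerate(order):
                assignment[ids[idx]] = pos % k
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricSet:
    """Confusion counts with the three derived rates (None when undefined)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def accuracy(self):
        n = self.TP + self.TN + self.FP + self.FN
        return None if n == 0 else (self.TP + self.TN) / n

    @property
    def sensitivity(self):
        n = self.TP + self.FN
        return None if n == 0 else self.TP / n

    @property
    def specificity(self):
        n = self.TN + self.FP
        return None if n == 0 else self.TN / n

    def to_dict(self) -> dict:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compute_metrics(TP: int, TN: int, FP: int, FN: int) -> MetricSet:
    if min(TP, TN, FP, FN) < 0:
        raise ValueError("confusion counts must be nonnegative")
    return MetricSet(TP=TP, TN=TN, FP=FP, FN=FN)


def metrics_from_predictions(pred: pd.DataFrame) -> MetricSet:
    """Confusion counts from a predictions frame with true/predicted labels."""
    y, yhat = pred["true_label"].to_numpy(), pred["predicted_label"].to_numpy()
    return compute_metrics(
        TP=int(np.sum((y == 1) & (yhat == 1))),
        TN=int(np.sum((y == -1) & (yhat == -1))),
        FP=int(np.sum((y == -1) & (yhat == 1))),
        FN=int(np.sum((y == 1) & (yhat == -1))),
    )


# ---------------------------------------------------------------------------
# Fitting a full pipeline model (screen -> stats -> LP)
# ---------------------------------------------------------------------------


@dataclass
class PipelineModel:
    """Screened, fitted multi-task discriminant ready to score new subjects."""

    model: MLPDModel
    method: str
    tau: float | None
    kept_counts: dict = field(default_factory=dict)  # task_id -> kept feature count
    task_ids: list = field(default_factory=list)

    def predict_dataset(self, ds: MultiSourceDataset, rows=None, *, strict: bool = True) -> pd.DataFrame:
        """Score subjects of ``ds`` (all rows by default) by pattern routing.

        With ``strict=False`` subjects whose pattern matches no fitted task
        are silently skipped instead of raising.
        """
        if rows is None:
            rows = range(ds.n_subjects)
        recs = []
        for r in rows:
            pattern = ds.pattern_of(r)
            hit = None
            for i, pat in enumerate(self.model.patterns):
                if pat == pattern:
                    hit = i
                    break
            if hit is None:
                if strict:
                    raise PatternMismatchError(
                        f"no model for availability pattern {sorted(pattern)}"
                    )
                continue
            x = ds.values[r, self.model.feature_index[hit]]
            score = float((x - self.model.mids[hit]) @ self.model.betas[hit])
            recs.append(
                {
                    "subject_id": ds.subject_ids[r],
                    "task_id": self.task_ids[hit],
                    "score": score,
                    "predicted_label": 1 if score > 0 else -1,
                    "true_label": int(ds.labels[r]),
                }
            )
        return pd.DataFrame(
            recs, columns=["subject_id", "task_id", "score", "predicted_label", "true_label"]
        )


@dataclass
class _Prepared:
    """Screened tasks with their statistics; everything a fit needs."""

    tasks: list
    stats: list
    shared: list


def _prepare(
    train: MultiSourceDataset,
    *,
    tau: float | None,
    min_per_class: int,
    t_variant: str = "pooled",
) -> _Prepared:
    tasks = decompose_tasks(train, min_per_class=min_per_class)
    if tau is not None:
        screening = screen_tasks(tasks, tau, variant=t_variant)
        tasks = [t.restrict_features(screening.kept_by_task[t.task_id]) for t in tasks]
    stats = [pooled_stats(t) for t in tasks]
    shared = [
        s
        for s in (shared_feature_set(a, b) for a, b in itertools.combinations(tasks, 2))
        if s.m > 0
    ]
    return _Prepared(tasks=tasks, stats=stats, shared=shared)


def _fit_prepared(
    prep: _Prepared, method: str, lambdas, gamma, *, tau, link_norm: str
) -> PipelineModel:
    tasks, stats = prep.tasks, prep.stats
    lam = np.broadcast_to(np.atleast_1d(np.asarray(lambdas, dtype=float)), (len(tasks),))
    if method == "mlpd":
        g = default_gamma(stats) if gamma is None else float(gamma)
        model = fit_mlpd(
            stats,
            prep.shared,
            lam,
            g,
            link_norm=link_norm,
            feature_index=[t.global_index for t in tasks],
            patterns=[t.pattern for t in tasks],
        )
    else:
        fits = [fit_slpd(s, l) for s, l in zip(stats, lam)]
        model = MLPDModel(
            betas=[f.beta for f in fits],
            mids=[f.mid for f in fits],
            lambdas=[float(l) for l in lam],
            gamma=0.0,
            objective=float(sum(f.objective for f in fits)),
            l1_part=float(sum(f.objective for f in fits)),
            link_part=0.0,
            feature_index=[t.global_index for t in tasks],
            patterns=[t.pattern for t in tasks],
        )
    return PipelineModel(
        model=model,
        method=method,
        tau=tau,
        kept_counts={t.task_id: t.p for t in tasks},
        task_ids=[t.task_id for t in tasks],
    )


def fit_pipeline(
    train: MultiSourceDataset,
    method: str,
    lambdas,
    gamma=None,
    *,
    tau: float | None = 0.01,
    min_per_class: int = 2,
    link_norm: str = "l1",
    t_variant: str = "pooled",
) -> PipelineModel:
    """Screen on the training subjects, then fit SLPD per task or MLPD jointly.

    ``lambdas`` is either a scalar (broadcast over tasks) or one value per
    task; ``gamma=None`` uses the dimension-scaled default for MLPD.
    """
    if method not in {"slpd", "mlpd"}:
        raise ValueError(f"unknown method {method!r}")
    prep = _prepare(train, tau=tau, min_per_class=min_per_class, t_variant=t_variant)
    return _fit_prepared(prep, method, lambdas, gamma, tau=tau, link_norm=link_norm)


# ---------------------------------------------------------------------------
# Inner CV parameter selection
# ---------------------------------------------------------------------------


def _candidates(n_tasks: int, method: str, lambda_grids, gamma_values):
    """Ordered candidate list; order encodes the sparsity-first tie-break."""
    if isinstance(lambda_grids, ParamGrid):
        lambda_grids = [lambda_grids]
    if method == "slpd":
        # one lambda shared across tasks
        lam_tuples = [(l,) * n_tasks for l in lambda_grids[0]]
    else:
        grids = lambda_grids if len(lambda_grids) == n_tasks else [lambda_grids[0]] * n_tasks
        lam_tuples = list(itertools.product(*[list(g) for g in grids]))
    gammas = list(gamma_values) if method == "mlpd" else [0.0]
    cands = [(lams, g) for lams in lam_tuples for g in gammas]
    cands.sort(key=lambda c: (c[0], math.inf if c[1] is None else c[1]))
    return cands


def inner_cv_select(
    train: MultiSourceDataset,
    method: str,
    lambda_grids,
    *,
    gamma_values=(None,),
    folds_inner: int = 5,
    seed: int = 0,
    tau: float | None = 0.01,
    min_per_class: int = 2,
    link_norm: str = "l1",
):
    """Pick (lambdas, gamma) maximizing mean inner-CV accuracy.

    Screening is recomputed on every inner training split.  Candidates whose
    LP is infeasible (or whose screening empties a task) on any inner split
    are skipped.  Ties break toward the smallest lambdas, then the smallest
    gamma.  Returns ``(lambdas, gamma, table)`` where ``table`` lists the
    mean inner accuracy per candidate.
    """
    tasks = decompose_tasks(train, min_per_class=min_per_class)
    folds = stratified_folds(tasks, folds_inner, seed)
    splits = []
    index = {s: i for i, s in enumerate(train.subject_ids)}
    for f in range(folds_inner):
        tr = train.subset([index[s] for s in sorted(folds.train_ids(f), key=index.get)])
        val_rows = sorted(index[s] for s in folds.test_ids(f))
        # screening and pooled statistics depend on the split only, not on
        # the candidate parameters; compute them once per split
        prep = _prepare(tr, tau=tau, min_per_class=min_per_class)
        splits.append((prep, val_rows))

    cands = _candidates(len(tasks), method, lambda_grids, gamma_values)
    table = []
    best = None
    for lams, g in cands:
        accs = []
        valid = True
        for prep, val_rows in splits:
            try:
                pm = _fit_prepared(prep, method, lams, g, tau=tau, link_norm=link_norm)
                pred = pm.predict_dataset(train, val_rows, strict=False)
            except (LPInfeasibleError, ScreeningEmptyError, MLPDError):
                valid = False
                break
            if len(pred) == 0:
                continue
            accs.append(float((pred.predicted_label == pred.true_label).mean()))
        if not valid or not accs:
            table.append({"lambdas": lams, "gamma": g, "mean_accuracy": None})
            continue
        mean_acc = float(np.mean(accs))
        table.append({"lambdas": lams, "gamma": g, "mean_accuracy": mean_acc})
        if best is None or mean_acc > best[2]:
            best = (lams, g, mean_acc)
    if best is None:
        raise MLPDError("no valid parameter point in the grid")
    return best[0], best[1], table


# ---------------------------------------------------------------------------
# Outer CV, repetitions
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    predictions: pd.DataFrame
    metrics: MetricSet
    metrics_by_task: dict
    fold_logs: list


def cross_validate(
    ds: MultiSourceDataset,
    method: str,
    k: int,
    seed: int,
    *,
    tau: float | None = 0.01,
    lambda_grids=None,
    gamma_values=(None,),
    inner_k: int = 5,
    min_per_class: int = 2,
    link_norm: str = "l1",
) -> CVResult:
    """One outer k-fold CV run with nested parameter selection."""
    if lambda_grids is None:
        lambda_grids = (
            make_log_grid(0.01, 1, 20) if method == "slpd" else make_log_grid(0.01, 10, 20)
        )
    tasks = decompose_tasks(ds, min_per_class=min_per_class)
    folds = stratified_folds(tasks, k, seed)
    rng = np.random.default_rng(seed)
    inner_seeds = rng.integers(2**31, size=k)
    index = {s: i for i, s in enumerate(ds.subject_ids)}

    all_pred = []
    fold_logs = []
    for f in range(k):
        train = ds.subset([index[s] for s in sorted(folds.train_ids(f), key=index.get)])
        test_rows = sorted(index[s] for s in folds.test_ids(f))
        lams, g, _ = inner_cv_select(
            train,
            method,
            lambda_grids,
            gamma_values=gamma_values,
            folds_inner=inner_k,
            seed=int(inner_seeds[f]),
            tau=tau,
            min_per_class=min_per_class,
            link_norm=link_norm,
        )
        pm = fit_pipeline(
            train, method, lams, g, tau=tau, min_per_class=min_per_class, link_norm=link_norm
        )
        pred = pm.predict_dataset(ds, test_rows, strict=False)
        pred.insert(1, "fold", f)
        all_pred.append(pred)
        fold_logs.append(
            {
                "fold": f,
                "inner_seed": int(inner_seeds[f]),
                "lambdas": [float(x) for x in lams],
                "gamma": None if g is None else float(g),
                "gamma_effective": float(pm.model.gamma),
                "kept_features": dict(pm.kept_counts),
                "n_train": train.n_subjects,
                "n_test": len(pred),
                "train_ids": list(train.subject_ids),
            }
        )
    predictions = pd.concat(all_pred, ignore_index=True)
    by_task = {
        int(tid): metrics_from_predictions(sub)
        for tid, sub in predictions.groupby("task_id")
    }
    return CVResult(
        predictions=predictions,
        metrics=metrics_from_predictions(predictions),
        metrics_by_task=by_task,
        fold_logs=fold_logs,
    )


def _summ(values):
    vals = [v for v in values if v is not None]
    if not vals:
        return {"mean": None, "sd": None}
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
    }


def repeated_cv_experiment(
    ds: MultiSourceDataset,
    k: int,
    method: str,
    reps: int = 30,
    base_seed: int = 0,
    **cv_kwargs,
) -> dict:
    """Repeat the full nested-CV pipeline; report mean/sd per metric.

    Repetition r re-randomizes outer folds and inner splits with seed
    ``base_seed + r``.  The summary covers the whole cohort and each task
    separately (the per-task view is what shows whether the incomplete
    subjects helped the complete-case classifier and vice versa).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    per_rep = []
    per_rep_by_task: dict = {}
    for r in range(reps):
        res = cross_validate(ds, method, k, base_seed + r, **cv_kwargs)
        per_rep.append(res.metrics.to_dict())
        for tid, m in res.metrics_by_task.items():
            per_rep_by_task.setdefault(tid, []).append(m.to_dict())
    metrics = ("accuracy", "sensitivity", "specificity")
    return {
        "overall": {m: _summ([d[m] for d in per_rep]) for m in metrics},
        "per_task": {
            tid: {m: _summ([d[m] for d in reps_list]) for m in metrics}
            for tid, reps_list in per_rep_by_task.items()
        },
        "per_rep": per_rep,
        "reps": reps,
        "k": k,
        "method": method,
        "base_seed": base_seed,
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline from a config
# ---------------------------------------------------------------------------

_PRESETS = {
    "two_block": synthetic.two_block_config,
    "single_block": synthetic.single_block_config,
    "paper_scale": synthetic.paper_scale_config,
}


def _load_dataset(config: dict) -> MultiSourceDataset:
    if "data" in config:
        d = config["data"]
        schema = read_schema(d["schema"])
        return read_feature_table(
            d["csv"],
            schema["sources"],
            schema.get("label_column", "label"),
            id_column=schema.get("id_column"),
            positive_label=schema.get("positive_label"),
        )
    if "simulate" in config:
        s = dict(config["simulate"])
        preset = s.pop("preset", "two_block")
        cfg = _PRESETS[preset](**s)
        return synthetic.simulate_dataset(cfg)
    raise MLPDError("config needs a 'data' or 'simulate' section")


def run_pipeline(config, out_dir=None) -> dict:
    """Run read/simulate -> CV evaluation -> artifacts on disk.

    ``config`` is a dict or a YAML path.  Artifacts: ``predictions.csv``
    (first repetition), ``metrics.json``, ``model.json`` (final model fitted
    on all data with parameters selected by inner CV), ``run.log``.
    Returns the metrics summary.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir or config.get("out", "mlpd_out"))
    out.mkdir(parents=True, exist_ok=True)

    ds = _load_dataset(config)
    if config.get("restrict_sources"):
        ds = restrict_sources(ds, config["restrict_sources"])
    if config.get("complete_cases"):
        ds = complete_cases(ds)

    method = config.get("method", "mlpd")
    k = int(config.get("k", 10))
    tau = config.get("tau", 0.01)
    seed = int(config.get("seed", 0))
    reps = int(config.get("reps", 1))
    inner_k = int(config.get("inner_k", 5))
    min_per_class = int(config.get("min_per_class", 2))
    link_norm = config.get("link_norm", "l1")

    gcfg = config.get("lambda_grid")
    if gcfg:
        lambda_grids = make_log_grid(float(gcfg["lo"]), float(gcfg["hi"]), int(gcfg["n"]))
    else:
        lambda_grids = None
    gam = config.get("gamma", {"policy": "fixed"})
    gamma_values = (
        tuple(float(v) for v in gam.get("values", []))
        if gam.get("policy") == "grid"
        else (gam.get("value"),)
    )

    cv_kwargs = dict(
        tau=tau,
        lambda_grids=lambda_grids,
        gamma_values=gamma_values,
        inner_k=inner_k,
        min_per_class=min_per_class,
        link_norm=link_norm,
    )
    summary = repeated_cv_experiment(ds, k, method, reps=reps, base_seed=seed, **cv_kwargs)

    first = cross_validate(ds, method, k, seed, **cv_kwargs)
    first.predictions.to_csv(out / "predictions.csv", index=False)

    lams, g, _ = inner_cv_select(
        ds,
        method,
        lambda_grids
        if lambda_grids is not None
        else (make_log_grid(0.01, 1, 20) if method == "slpd" else make_log_grid(0.01, 10, 20)),
        gamma_values=gamma_values,
        folds_inner=inner_k,
        seed=seed,
        tau=tau,
        min_per_class=min_per_class,
        link_norm=link_norm,
    )
    final = fit_pipeline(
        ds, method, lams, g, tau=tau, min_per_class=min_per_class, link_norm=link_norm
    )
    (out / "model.json").write_text(json.dumps(final.model.to_dict(), indent=2))
    (out / "metrics.json").write_text(json.dumps(summary, indent=2))

    log_lines = [f"method={method} k={k} tau={tau} reps={reps} seed={seed}"]
    for fl in first.fold_logs:
        log_lines.append(
            f"fold {fl['fold']}: lambdas={fl['lambdas']} gamma={fl['gamma_effective']:.6g} "
            f"kept={fl['kept_features']} n_train={fl['n_train']} n_test={fl['n_test']}"
        )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def simulate_to_files(preset: str, out_csv, out_schema, **options) -> MultiSourceDataset:
    """Draw a synthetic dataset and write the CSV + schema pair."""
    cfg = _PRESETS[preset](**options)
    ds = synthetic.simulate_dataset(cfg)
    write_feature_table(ds, out_csv)
    write_schema(ds, out_schema)
    return ds
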