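"""Two-sample t-test feature prescreening with asymmetric keep rules.

High-dimensional ROI panels carry many features with no class signal; a
univariate t-test pass removes the obviously uninformative ones before the
discriminant LP is solved.  The keep rules are deliberately asymmetric
across tasks: a task with fewer observed sources keeps a shared feature if
it is significant in *either* its own screening or that of a richer task.
The rationale: when sources are correlated, a feature that looks weak in the
smaller task may still be useful there, and the richer task's screening has
seen it in its multi-source context.

P-values are always computed on training subjects only; callers running
cross-validation re-screen inside every split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import TaskDataset
from .errors import ScreeningEmptyError

__all__ = ["ScreeningResult", "two_sample_t", "task_pvalues", "preselect_features", "screen_tasks"]


@dataclass
class ScreeningResult:
    """Per-task p-values and retained local feature positions (0-based)."""

    pvalues_by_task: dict  # task_id -> np.ndarray over that task's features
    tau: float
    kept_by_task: dict  # task_id -> sorted list of kept local positions


def two_sample_t(x1, x2, *, variant: str = "pooled"):
    """Two-sample t-statistic and two-sided p-value.

    ``variant="pooled"`` is the classic equal-variance test with
    ``df = n1 + n2 - 2``; ``variant="welch"`` uses the Welch correction.
    Degenerate inputs (both samples constant): equal means give ``(0, 1)``,
    different means give ``(+/-inf, 0)`` with a warning.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if variant not in {"pooled", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.ptp(x1) == 0 and np.ptp(x2) == 0:
        if x1[0] == x2[0]:
            return 0.0, 1.0
        warnings.warn("both samples constant with different means; p-value set to 0")
        return float(np.copysign(np.inf, x1[0] - x2[0])), 0.0
    res = stats.ttest_ind(x1, x2, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def task_pvalues(task: TaskDataset, *, variant: str = "pooled") -> np.ndarray:
    """Two-sided p-values of every feature of a task (class +1 vs class -1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(task.X1, task.X2, axis=0, equal_var=(variant == "pooled"))
        p = np.asarray(res.pvalue, dtype=float)
    # scipy yields NaN where both samples are constant; apply the degenerate rule
    bad = np.isnan(p)
    if bad.any():
        m1 = task.X1.mean(axis=0)
        m2 = task.X2.mean(axis=0)
        p[bad] = np.where(np.isclose(m1[bad], m2[bad]), 1.0, 0.0)
    return p


def preselect_features(p1, p2, tau: float, *, shared_positions=None) -> ScreeningResult:
    """Apply the two-task asymmetric keep rules.

    ``p1`` covers all features of task 1 (the richer pattern), ``p2`` the
    features of task 2, all of which are shared with task 1.
    ``shared_positions[j]`` gives the local position in task 1 of task 2's
    feature ``j`` (default: position ``j``, i.e. shared features first).

    Task 1 keeps feature ``j`` iff ``p1[j] <= tau``.  Task 2 keeps feature
    ``j`` iff ``p1[shared_positions[j]] <= tau`` *or* ``p2[j] <= tau`` —
    removal requires both screenings to fail, which keeps more features for
    the source-poorer task.  Ties at ``p == tau`` are kept.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if shared_positions is None:
        shared_positions = np.arange(len(p2))
    shared_positions = np.asarray(shared_positions, dtype=int)
    kept1 = np.flatnonzero(p1 <= tau)
    kept2 = np.flatnonzero((p1[shared_positions] <= tau) | (p2 <= tau))
    for tid, kept, total in ((1, kept1, len(p1)), (2, kept2, len(p2))):
        if kept.size == 0:
            raise ScreeningEmptyError(
                f"screening removed all {total} features of task {tid}; raise tau"
            )
    return ScreeningResult(
        pvalues_by_task={1: p1, 2: p2},
        tau=tau,
        kept_by_task={1: kept1.tolist(), 2: kept2.tolist()},
    )


def screen_tasks(tasks, tau: float, *, variant: str = "pooled") -> ScreeningResult:
    """Generalized screening over any number of tasks.

    A feature of task *i* is kept iff its p-value in task *i*'s own screening
    is <= tau, or the same global feature passes the screening of some task
    with strictly more sources.  For the canonical two-task instance (task 1
    both sources, task 2 one source) this reduces exactly to the asymmetric
    rules of :func:`preselect_features`.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    pvals = {t.task_id: task_pvalues(t, variant=variant) for t in tasks}
    # global feature id -> p-value, per task
    by_global = {
        t.task_id: dict(zip(t.global_index.tolist(), pvals[t.task_id])) for t in tasks
    }
    kept = {}
    for t in tasks:
        rescuers = [u for u in tasks if len(u.pattern) > len(t.pattern)]
        keep = []
        for l, g in enumerate(t.global_index.tolist()):
            if pvals[t.task_id][l] <= tau or any(
                g in by_global[u.task_id] and by_global[u.task_id][g] <= tau
                for u in rescuers
            ):
                keep.append(l)
        if not keep:
            raise ScreeningEmptyError(
                f"screening removed all features of task {t.task_id}; raise tau"
            )
        kept[t.task_id] = keep
    return ScreeningResult(pvalues_by_task=pvals, tau=tau, kept_by_task=kept)
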