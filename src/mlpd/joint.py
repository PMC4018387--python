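"""Multi-task Linear Programming Discriminant (MLPD): the joint LP.

Each task i (one availability pattern) contributes a Dantzig-type fidelity
constraint on its own discriminant vector; a linking penalty couples tasks
through their shared features.  ``(sigma_i beta_i)_k`` estimates the
population mean difference of feature k in task i, so for a feature shared
by tasks i and j the two estimates should agree; the joint program is

    minimize  sum_i ||beta_i||_1
              + gamma * sum_{pairs (i,j)} sum_{k in S_ij}
                        |(sigma_i beta_i)_k - (sigma_j beta_j)_k|
    subject to ||sigma_i beta_i - delta_i||_inf <= lambda_i   for every i.

With gamma = 0 the program separates into independent single-task LPD fits.
The absolute values are linearized in the standard way (beta = beta+ - beta-
splits plus one nonnegative slack per linked shared feature), giving a plain
LP solved by HiGHS.  An l_inf variant of the linking term (one slack per
task pair, bounding the worst shared-feature disagreement) is available via
``link_norm="linf"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import SharedFeatureSet
from .errors import MLPDError, PatternMismatchError
from .slpd import ClassStats, LPDModel, _solve_lp, classify_lpd

__all__ = ["LPSpec", "MLPDModel", "build_joint_lp", "fit_mlpd", "classify_mlpd", "default_gamma"]


@dataclass
class LPSpec:
    """Explicit joint LP with row/column provenance labels.

    Variable layout: per task i, blocks ``beta+_i`` then ``beta-_i`` (p_i
    each); then one slack block per linked task pair (m slacks for the l1
    linking norm, 1 for the l_inf variant).
    """

    c: np.ndarray
    A_ub: np.ndarray
    b_ub: np.ndarray
    var_labels: list
    row_labels: list
    beta_slices: dict  # task position -> (slice of beta+, slice of beta-)
    link_slices: dict  # pair position -> slice of slack variables
    link_norm: str


def _resolve_pair(pair, n_tasks):
    """Map a SharedFeatureSet's 1-based task ids to positions in the stats list."""
    i, j = pair
    if not (1 <= i <= n_tasks and 1 <= j <= n_tasks):
        raise MLPDError(f"shared set references task pair {pair}, but {n_tasks} tasks given")
    return i - 1, j - 1


def default_gamma(stats) -> float:
    """Default linking weight: 1 / max_i p_i.

    Scales the linking term so its per-feature contribution is comparable to
    the l1 objective regardless of dimension; override via config or tuning.
    """
    return 1.0 / max(s.p for s in stats)


def build_joint_lp(stats, shared, lambdas, gamma, *, link_norm: str = "l1") -> LPSpec:
    """Assemble the joint LP (objective, inequality system, labels).

    ``stats`` is the per-task :class:`ClassStats` list in task-id order
    (task i at position i-1); ``shared`` lists :class:`SharedFeatureSet`
    objects whose ``task_pair`` holds the 1-based task ids, as produced by
    :func:`mlpd.datamodel.shared_feature_set`.
    """
    lambdas = [float(l) for l in np.atleast_1d(lambdas)]
    if len(lambdas) != len(stats):
        raise MLPDError(f"{len(stats)} tasks but {len(lambdas)} lambdas")
    if any(l < 0 for l in lambdas):
        raise ValueError("lambdas must be nonnegative")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if link_norm not in {"l1", "linf"}:
        raise ValueError(f"unknown link_norm {link_norm!r}")

    ps = [s.p for s in stats]
    n_beta = 2 * sum(ps)
    beta_slices = {}
    var_labels = []
    off = 0
    for i, p in enumerate(ps):
        beta_slices[i] = (slice(off, off + p), slice(off + p, off + 2 * p))
        var_labels += [f"beta+[task={i},f={l}]" for l in range(p)]
        var_labels += [f"beta-[task={i},f={l}]" for l in range(p)]
        off += 2 * p

    link_slices = {}
    shared = [s for s in shared if s.m > 0]
    for q, s in enumerate(shared):
        width = s.m if link_norm == "l1" else 1
        link_slices[q] = slice(off, off + width)
        var_labels += [f"t[pair={s.task_pair},k={k}]" for k in range(width)]
        off += width
    n_var = off

    c = np.zeros(n_var)
    c[:n_beta] = 1.0
    for q in link_slices:
        c[link_slices[q]] = gamma

    rows, b, row_labels = [], [], []

    def _beta_row(i, sigma_row):
        """Coefficients of (sigma_i beta_i)_row over the full variable vector."""
        r = np.zeros(n_var)
        up, vn = beta_slices[i]
        r[up] = sigma_row
        r[vn] = -sigma_row
        return r

    # fidelity: |sigma_i beta_i - delta_i| <= lambda_i, componentwise
    for i, s in enumerate(stats):
        for l in range(s.p):
            base = _beta_row(i, s.sigma[l])
            rows.append(base)
            b.append(lambdas[i] + s.delta[l])
            row_labels.append(f"fidelity[task={i},f={l},+]")
            rows.append(-base)
            b.append(lambdas[i] - s.delta[l])
            row_labels.append(f"fidelity[task={i},f={l},-]")

    # linking: |(sigma_i beta_i)_a - (sigma_j beta_j)_b| <= t
    for q, s in enumerate(shared):
        i, j = _resolve_pair(s.task_pair, len(stats))
        for k, (a, bb) in enumerate(s.pairs):
            diff = _beta_row(i, stats[i].sigma[a]) - _beta_row(j, stats[j].sigma[bb])
            slack = link_slices[q].start + (k if link_norm == "l1" else 0)
            for sign, tag in ((1.0, "+"), (-1.0, "-")):
                r = sign * diff
                r[slack] = -1.0
                rows.append(r)
                b.append(0.0)
                row_labels.append(f"link[pair={s.task_pair},k={k},{tag}]")

    return LPSpec(
        c=c,
        A_ub=np.array(rows) if rows else np.zeros((0, n_var)),
        b_ub=np.array(b),
        var_labels=var_labels,
        row_labels=row_labels,
        beta_slices=beta_slices,
        link_slices=link_slices,
        link_norm=link_norm,
    )


@dataclass
class MLPDModel:
    """Fitted joint discriminant: one vector per task plus tuning state."""

    betas: list  # per-task np.ndarray
    mids: list
    lambdas: list
    gamma: float
    shared: list = field(default_factory=list)
    objective: float = 0.0
    l1_part: float = 0.0
    link_part: float = 0.0
    feature_index: list = field(default_factory=list)  # per-task global ids (or None)
    patterns: list = field(default_factory=list)  # per-task frozenset of source names
    solver_status: dict = field(default_factory=dict)

    @property
    def n_tasks(self) -> int:
        return len(self.betas)

    def task_model(self, i: int) -> LPDModel:
        """View of task i as a single-task model (for scoring)."""
        return LPDModel(
            beta=self.betas[i],
            mid=self.mids[i],
            lam=self.lambdas[i],
            feature_index=self.feature_index[i] if self.feature_index else None,
        )

    def to_dict(self) -> dict:
        return {
            "betas": [b.tolist() for b in self.betas],
            "mids": [m.tolist() for m in self.mids],
            "lambdas": list(self.lambdas),
            "gamma": self.gamma,
            "objective": self.objective,
            "l1_part": self.l1_part,
            "link_part": self.link_part,
            "feature_index": [
                None if f is None else np.asarray(f).tolist() for f in self.feature_index
            ],
            "patterns": [sorted(p) for p in self.patterns],
            "solver_status": self.solver_status,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPDModel":
        return cls(
            betas=[np.asarray(b, dtype=float) for b in d["betas"]],
            mids=[np.asarray(m, dtype=float) for m in d["mids"]],
            lambdas=[float(l) for l in d["lambdas"]],
            gamma=float(d["gamma"]),
            objective=float(d.get("objective", 0.0)),
            l1_part=float(d.get("l1_part", 0.0)),
            link_part=float(d.get("link_part", 0.0)),
            feature_index=[
                None if f is None else np.asarray(f, dtype=int)
                for f in d.get("feature_index", [])
            ],
            patterns=[frozenset(p) for p in d.get("patterns", [])],
        )


def fit_mlpd(stats, shared, lambdas, gamma, *, link_norm: str = "l1",
             feature_index=None, patterns=None) -> MLPDModel:
    """Solve the joint LP and unpack per-task discriminant vectors."""
    spec = build_joint_lp(stats, shared, lambdas, gamma, link_norm=link_norm)
    res = _solve_lp(spec.c, spec.A_ub, spec.b_ub, "fit_mlpd")
    betas = []
    for i in range(len(stats)):
        up, vn = spec.beta_slices[i]
        betas.append(res.x[up] - res.x[vn])
    l1_part = float(sum(np.abs(b).sum() for b in betas))
    link_part = _link_penalty(stats, shared, betas)
    return MLPDModel(
        betas=betas,
        mids=[s.mid for s in stats],
        lambdas=[float(l) for l in np.atleast_1d(lambdas)],
        gamma=float(gamma),
        shared=list(shared),
        objective=float(res.fun),
        l1_part=l1_part,
        link_part=link_part,
        feature_index=list(feature_index) if feature_index is not None else [None] * len(stats),
        patterns=list(patterns) if patterns is not None else [],
        solver_status={"status": int(res.status), "message": res.message, "nit": int(res.nit)},
    )


def _link_penalty(stats, shared, betas) -> float:
    """Sum over linked shared features of |(sigma_i b_i)_k - (sigma_j b_j)_k|."""
    total = 0.0
    for s in shared:
        if s.m == 0:
            continue
        i, j = _resolve_pair(s.task_pair, len(stats))
        fi = stats[i].sigma @ betas[i]
        fj = stats[j].sigma @ betas[j]
        for a, b in s.pairs:
            total += abs(fi[a] - fj[b])
    return float(total)


def classify_mlpd(m: MLPDModel, x, pattern):
    """Route a subject to the task fitted for its availability pattern.

    ``x`` must hold exactly that task's (screened) features.  A pattern with
    no fitted task raises :class:`PatternMismatchError`.
    """
    pattern = frozenset(pattern)
    if not m.patterns:
        raise MLPDError("model carries no pattern metadata; score via task_model(i)")
    for i, pat in enumerate(m.patterns):
        if pat == pattern:
            return classify_lpd(m.task_model(i), x)
    raise PatternMismatchError(f"no model for availability pattern {sorted(pattern)}")
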