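"""Single-task Linear Programming Discriminant (SLPD) rule.

Fisher's rule classifies by the sign of ``(x - mu)' Sigma^{-1} delta`` with
``delta = mu1 - mu2`` and ``mu = (mu1 + mu2)/2``.  In high dimension the
sample covariance is singular, so instead of inverting it the LPD rule
estimates the product ``beta = Sigma^{-1} delta`` directly by a Dantzig-type
constrained l1 program:

    minimize ||beta||_1   subject to   ||Sigma_hat beta - delta_hat||_inf <= lambda

which is solved exactly as a linear program after the split
``beta = beta+ - beta-`` (2p nonnegative variables, 2p inequality rows).
``lambda`` trades fidelity to the sample statistics against sparsity and is
chosen by cross-validation.  A new subject x is assigned to the positive
class iff ``(x - mid)' beta > 0`` (ties go to the negative class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .datamodel import TaskDataset
from .errors import LPInfeasibleError, SolverError

__all__ = ["ClassStats", "LPDModel", "pooled_stats", "class_stats", "fit_slpd", "classify_lpd"]

#: primal/dual feasibility tolerance passed to the HiGHS solver
SOLVER_TOL = 1e-8
#: slack allowed when verifying the infinity-norm fidelity constraint post hoc
CONSTRAINT_TOL = 1e-6


@dataclass
class ClassStats:
    """Sufficient statistics of one two-class task.

    ``sigma`` is the maximum-likelihood pooled covariance: within-class
    centered scatter of both classes divided by the total sample size n
    (not n - 2); the difference is absorbed by the scale of lambda.
    """

    mu1: np.ndarray
    mu2: np.ndarray
    sigma: np.ndarray
    n1: int
    n2: int

    @property
    def delta(self) -> np.ndarray:
        return self.mu1 - self.mu2

    @property
    def mid(self) -> np.ndarray:
        return (self.mu1 + self.mu2) / 2.0

    @property
    def p(self) -> int:
        return len(self.mu1)


def class_stats(X1, X2) -> ClassStats:
    """Pooled statistics from the two class matrices."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n1, n2 = X1.shape[0], X2.shape[0]
    mu1 = X1.mean(axis=0)
    mu2 = X2.mean(axis=0)
    C1 = X1 - mu1
    C2 = X2 - mu2
    sigma = (C1.T @ C1 + C2.T @ C2) / (n1 + n2)
    sigma = (sigma + sigma.T) / 2.0  # enforce exact symmetry
    return ClassStats(mu1=mu1, mu2=mu2, sigma=sigma, n1=n1, n2=n2)


def pooled_stats(t: TaskDataset) -> ClassStats:
    return class_stats(t.X1, t.X2)


@dataclass
class LPDModel:
    """Fitted single-task discriminant: direction, midpoint, tuning state."""

    beta: np.ndarray
    mid: np.ndarray
    lam: float
    feature_index: np.ndarray | None = None
    objective: float = 0.0
    solver_status: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "mid": self.mid.tolist(),
            "lambda": self.lam,
            "feature_index": None
            if self.feature_index is None
            else np.asarray(self.feature_index).tolist(),
            "objective": self.objective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LPDModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            mid=np.asarray(d["mid"], dtype=float),
            lam=float(d["lambda"]),
            feature_index=None
            if d.get("feature_index") is None
            else np.asarray(d["feature_index"], dtype=int),
            objective=float(d.get("objective", 0.0)),
        )


def _solve_lp(c, A_ub, b_ub, context: str):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=(0, None),
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    if res.status == 2:
        raise LPInfeasibleError(f"{context}: LP infeasible (lambda too small?)")
    if res.status != 0:
        raise SolverError(f"{context}: solver status {res.status} ({res.message})")
    return res


def fit_slpd(s: ClassStats, lam: float, *, feature_index=None) -> LPDModel:
    """Solve ``min ||beta||_1 s.t. ||sigma beta - delta||_inf <= lam`` exactly.

    Raises :class:`LPInfeasibleError` when no beta satisfies the fidelity
    band (possible for singular sigma with small lam); parameter tuning
    treats that as an invalid lambda.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = s.p
    sigma, delta = s.sigma, s.delta
    # variables [beta+, beta-]; rows: sigma(beta+ - beta-) - delta <= lam (both signs)
    c = np.ones(2 * p)
    A_ub = np.block([[sigma, -sigma], [-sigma, sigma]])
    b_ub = np.concatenate([lam + delta, lam - delta])
    res = _solve_lp(c, A_ub, b_ub, "fit_slpd")
    beta = res.x[:p] - res.x[p:]
    return LPDModel(
        beta=beta,
        mid=s.mid,
        lam=float(lam),
        feature_index=None if feature_index is None else np.asarray(feature_index, dtype=int),
        objective=float(res.fun),
        solver_status={"status": int(res.status), "message": res.message, "nit": int(res.nit)},
    )


def classify_lpd(m: LPDModel, x):
    """Score and label one subject: ``score = (x - mid)' beta``, +1 iff > 0."""
    x = np.asarray(x, dtype=float)
    if x.shape != m.mid.shape:
        raise ValueError(f"feature vector has shape {x.shape}, expected {m.mid.shape}")
    score = float((x - m.mid) @ m.beta)
    return score, (1 if score > 0 else -1)
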