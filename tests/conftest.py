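"""Shared fixtures: random problem generators and an independent LP oracle."""

import numpy as np
import pytest
from scipy.optimize import linprog

from mlpd import MultiSourceDataset, SharedFeatureSet
from mlpd.slpd import ClassStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240512)


def random_stats(rng, p, n1=8, n2=8):
    """Well-conditioned random task statistics (sigma PSD by construction)."""
    A = rng.standard_normal((2 * p, p))
    sigma = A.T @ A / (2 * p) + 0.1 * np.eye(p)
    return ClassStats(
        mu1=rng.standard_normal(p),
        mu2=rng.standard_normal(p),
        sigma=(sigma + sigma.T) / 2,
        n1=n1,
        n2=n2,
    )


def random_two_task_instance(rng, p1=3, p2=2, m=None):
    """Two random tasks sharing the first m features (ids are 1 and 2)."""
    if m is None:
        m = int(rng.integers(0, min(p1, p2) + 1))
    s1 = random_stats(rng, p1)
    s2 = random_stats(rng, p2)
    shared = SharedFeatureSet(task_pair=(1, 2), pairs=[(k, k) for k in range(m)])
    return s1, s2, shared


def reference_joint_objective(stats, shared, lambdas, gamma):
    """Independent generic LP for the joint problem (free-variable encoding).

    Variables: beta_i free, a_i >= |beta_i| slacks, t >= linking residuals.
    Deliberately different from the package's beta+/beta- split so it can
    serve as a cross-check oracle.  Returns the optimal objective value.
    """
    ps = [s.p for s in stats]
    n_beta = sum(ps)
    off_beta = np.cumsum([0] + ps)
    m_tot = sum(s.m for s in shared)
    n_var = 2 * n_beta + m_tot  # [beta, a, t]

    c = np.zeros(n_var)
    c[n_beta : 2 * n_beta] = 1.0
    c[2 * n_beta :] = gamma

    rows, b = [], []

    def beta_cols(i):
        return slice(off_beta[i], off_beta[i + 1])

    # |beta| <= a
    for j in range(n_beta):
        r = np.zeros(n_var)
        r[j] = 1.0
        r[n_beta + j] = -1.0
        rows.append(r)
        b.append(0.0)
        r = np.zeros(n_var)
        r[j] = -1.0
        r[n_beta + j] = -1.0
        rows.append(r)
        b.append(0.0)

    # fidelity
    for i, s in enumerate(stats):
        for l in range(s.p):
            r = np.zeros(n_var)
            r[beta_cols(i)] = s.sigma[l]
            rows.append(r.copy())
            b.append(lambdas[i] + s.delta[l])
            rows.append(-r)
            b.append(lambdas[i] - s.delta[l])

    # linking
    t_off = 2 * n_beta
    for sh in shared:
        i, j = sh.task_pair[0] - 1, sh.task_pair[1] - 1
        for k, (ai, bj) in enumerate(sh.pairs):
            r = np.zeros(n_var)
            r[beta_cols(i)] = stats[i].sigma[ai]
            r[beta_cols(j)] -= stats[j].sigma[bj]
            for sign in (1.0, -1.0):
                rr = sign * r
                rr[t_off + k] = -1.0
                rows.append(rr)
                b.append(0.0)
        t_off += sh.m

    bounds = [(None, None)] * n_beta + [(0, None)] * (n_beta + m_tot)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(b), bounds=bounds, method="highs")
    if res.status == 2:
        return None  # infeasible
    assert res.status == 0, res.message
    return float(res.fun)


def tiny_two_source_dataset(n_both=(12, 12), n_first=(12, 12), p_block=3, seed=0, effect=1.0):
    """Small two-source dataset with a plain mean shift, for pipeline tests."""
    rng = np.random.default_rng(seed)
    p = 2 * p_block
    sources = [("A", [f"A_{i}" for i in range(p_block)]), ("B", [f"B_{i}" for i in range(p_block)])]
    mu1 = np.zeros(p)
    mu1[:2] = effect
    rows, labels, avail = [], [], []
    for pat, (npos, nneg) in ((("A", "B"), n_both), (("A",), n_first)):
        for lab, n in ((1, npos), (-1, nneg)):
            X = rng.standard_normal((n, p)) + (mu1 if lab == 1 else 0)
            if pat == ("A",):
                X[:, p_block:] = np.nan
            rows.append(X)
            labels += [lab] * n
            avail += [[True, pat != ("A",)]] * n
    values = np.vstack(rows)
    return MultiSourceDataset(
        subject_ids=[f"s{i}" for i in range(len(labels))],
        labels=np.array(labels),
        sources=sources,
        values=values,
        availability=np.array(avail),
    )
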