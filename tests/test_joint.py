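"""Joint multi-task LP: structure, decoupling, linking behaviour, routing."""

import numpy as np
import pytest

from mlpd import (
    PatternMismatchError,
    SharedFeatureSet,
    build_joint_lp,
    classify_lpd,
    classify_mlpd,
    fit_mlpd,
    fit_slpd,
)
from mlpd.joint import _link_penalty

from conftest import random_stats, random_two_task_instance, reference_joint_objective


class TestBuildJointLp:
    def test_variable_and_row_counts(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2, m=2)
        spec = build_joint_lp([s1, s2], [sh], [0.5, 0.5], 1.0)
        assert spec.A_ub.shape[1] == 2 * (3 + 2) + 2  # beta splits + linking slacks
        fidelity = [r for r in spec.row_labels if r.startswith("fidelity")]
        linking = [r for r in spec.row_labels if r.startswith("link")]
        assert len(fidelity) == 2 * (3 + 2)
        assert len(linking) == 2 * 2

    def test_gamma_zero_slacks_cost_nothing(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2, m=2)
        spec = build_joint_lp([s1, s2], [sh], [0.5, 0.5], 0.0)
        slack_cols = spec.link_slices[0]
        np.testing.assert_array_equal(spec.c[slack_cols], 0.0)

    def test_no_shared_features_no_linking_rows(self, rng):
        s1, s2, _ = random_two_task_instance(rng, p1=3, p2=2, m=0)
        sh = SharedFeatureSet(task_pair=(1, 2), pairs=[])
        spec = build_joint_lp([s1, s2], [sh], [0.5, 0.5], 2.0)
        assert not any(r.startswith("link") for r in spec.row_labels)
        assert spec.A_ub.shape == (2 * (3 + 2), 2 * (3 + 2))

    def test_linf_variant_uses_one_slack_per_pair(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=3, m=3)
        spec = build_joint_lp([s1, s2], [sh], [0.5, 0.5], 1.0, link_norm="linf")
        assert spec.link_slices[0].stop - spec.link_slices[0].start == 1


class TestFitMlpd:
    def test_gamma_zero_decouples_to_slpd(self, rng):
        for _ in range(50):
            p1, p2 = int(rng.integers(2, 7)), int(rng.integers(2, 5))
            s1, s2, sh = random_two_task_instance(rng, p1=p1, p2=p2)
            lams = [float(rng.uniform(0.1, 0.6)) for _ in range(2)]
            joint = fit_mlpd([s1, s2], [sh], lams, 0.0)
            sep = fit_slpd(s1, lams[0]).objective + fit_slpd(s2, lams[1]).objective
            assert joint.objective == pytest.approx(sep, abs=1e-6)

    def test_identical_tasks_fully_shared(self, rng):
        s = random_stats(rng, 4)
        sh = SharedFeatureSet(task_pair=(1, 2), pairs=[(k, k) for k in range(4)])
        single = fit_slpd(s, 0.3).objective
        for gamma in (0.0, 0.5, 5.0):
            joint = fit_mlpd([s, s], [sh], [0.3, 0.3], gamma)
            assert joint.objective == pytest.approx(2 * single, abs=1e-6)
            assert joint.link_part == pytest.approx(0.0, abs=1e-6)

    def test_matches_reference_solver(self, rng):
        for _ in range(100):
            s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2)
            lams = [float(rng.uniform(0.1, 0.6)), float(rng.uniform(0.1, 0.6))]
            gamma = float(rng.uniform(0.0, 3.0))
            ref = reference_joint_objective([s1, s2], [sh], lams, gamma)
            joint = fit_mlpd([s1, s2], [sh], lams, gamma)
            assert ref is not None
            assert joint.objective == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_gamma(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=4, p2=3, m=3)
        gammas = [0.0, 0.2, 0.5, 1.0, 3.0, 10.0]
        fits = [fit_mlpd([s1, s2], [sh], [0.3, 0.3], g) for g in gammas]
        l1 = [f.l1_part for f in fits]
        link = [f.link_part for f in fits]
        assert all(a <= b + 1e-7 for a, b in zip(l1, l1[1:]))
        assert all(a >= b - 1e-7 for a, b in zip(link, link[1:]))

    def test_large_gamma_drives_linking_residual_to_zero(self, rng):
        # both tasks see the same statistics, so exact agreement is feasible
        s = random_stats(rng, 3)
        sh = SharedFeatureSet(task_pair=(1, 2), pairs=[(k, k) for k in range(3)])
        joint = fit_mlpd([s, s], [sh], [0.4, 0.4], 1e6)
        assert joint.link_part <= 1e-4

    def test_task_relabeling_leaves_objective_unchanged(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2, m=2)
        fwd = fit_mlpd([s1, s2], [sh], [0.3, 0.4], 0.7)
        sh_rev = SharedFeatureSet(task_pair=(2, 1), pairs=[(b, a) for a, b in sh.pairs])
        rev = fit_mlpd([s2, s1], [sh_rev], [0.4, 0.3], 0.7)
        assert fwd.objective == pytest.approx(rev.objective, abs=1e-6)

    def test_shared_pair_order_irrelevant(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=4, p2=4, m=4)
        shuffled = SharedFeatureSet(task_pair=(1, 2), pairs=list(reversed(sh.pairs)))
        a = fit_mlpd([s1, s2], [sh], [0.3, 0.3], 0.9)
        b = fit_mlpd([s1, s2], [shuffled], [0.3, 0.3], 0.9)
        assert a.objective == pytest.approx(b.objective, abs=1e-6)

    def test_fidelity_invariants_hold_per_task(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=4, p2=3, m=2)
        joint = fit_mlpd([s1, s2], [sh], [0.25, 0.35], 1.5)
        for s, beta, lam in zip((s1, s2), joint.betas, (0.25, 0.35)):
            assert np.max(np.abs(s.sigma @ beta - s.delta)) <= lam + 1e-6

    def test_link_penalty_helper_matches_objective_split(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=3, m=2)
        joint = fit_mlpd([s1, s2], [sh], [0.3, 0.3], 0.8)
        pen = _link_penalty([s1, s2], [sh], joint.betas)
        # the solver's objective = l1 part + gamma * slack total; slacks sit
        # exactly at the absolute residuals at any optimum with gamma > 0
        assert joint.objective == pytest.approx(joint.l1_part + 0.8 * pen, abs=1e-6)


class TestClassifyMlpd:
    def test_routes_by_pattern_and_reduces_to_slpd(self, rng):
        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2, m=2)
        joint = fit_mlpd(
            [s1, s2],
            [sh],
            [0.3, 0.3],
            0.0,
            patterns=[frozenset({"MRI", "PET"}), frozenset({"MRI"})],
        )
        single = fit_slpd(s2, 0.3)
        x = rng.standard_normal(2)
        score_joint, label_joint = classify_mlpd(joint, x, {"MRI"})
        score_single, label_single = classify_lpd(single, x)
        assert score_joint == pytest.approx(score_single, abs=1e-6)
        assert label_joint == label_single

    def test_zero_beta_tie_goes_negative(self, rng):
        s = random_stats(rng, 2)
        from mlpd.slpd import ClassStats

        s0 = ClassStats(mu1=s.mu1, mu2=s.mu1, sigma=s.sigma, n1=4, n2=4)
        joint = fit_mlpd([s0], [], [0.2], 0.0, patterns=[frozenset({"A"})])
        _, label = classify_mlpd(joint, s.mu1, {"A"})
        assert label == -1

    def test_unknown_pattern_raises(self, rng):
        s = random_stats(rng, 2)
        joint = fit_mlpd([s], [], [0.2], 0.0, patterns=[frozenset({"A"})])
        with pytest.raises(PatternMismatchError):
            classify_mlpd(joint, np.zeros(2), {"B"})

    def test_serialization_roundtrip(self, rng):
        from mlpd import MLPDModel

        s1, s2, sh = random_two_task_instance(rng, p1=3, p2=2, m=1)
        joint = fit_mlpd([s1, s2], [sh], [0.3, 0.4], 0.5,
                         patterns=[frozenset({"A", "B"}), frozenset({"A"})])
        back = MLPDModel.from_dict(joint.to_dict())
        for a, b in zip(joint.betas, back.betas):
            np.testing.assert_allclose(a, b)
        assert back.gamma == joint.gamma
        assert back.patterns == joint.patterns
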