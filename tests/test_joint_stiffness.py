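"""Joint stiffness assembly: oracle equivalence, additivity, closed forms."""

import numpy as np
import pytest

from ccistiff.geometry import MuscleGeometryPoly
from ccistiff.joint_stiffness import (
    contribution_fractions,
    joint_moment,
    muscle_stiffness,
    stiffness_series,
)
from ccistiff.musculotendon import MuscleParams, tendon_force_slope
from ccistiff.subject import MuscleEntry, SubjectLegModel

DOF = "knee_flexion"


def one_muscle_leg(lin, quad=0.0, l_opt=0.10, l_tilde0=0.95, alpha=0.0,
                   f_max=1000.0, name="m1", extra=()):
    """Single-DOF leg with controllable geometry and operating point."""
    muscles = []
    for i, (li, qi) in enumerate([(lin, quad)] + list(extra)):
        c0 = 0.40
        x0 = l_tilde0 * l_opt * np.cos(np.arcsin(np.sin(alpha) / l_tilde0))
        geom = MuscleGeometryPoly(
            dof_labels=(DOF,), coefficients={(0,): c0, (1,): li, (2,): qi}
        )
        muscles.append(
            MuscleEntry(
                name=f"m{i + 1}",
                emg_source=f"src{i}",
                roles={},
                params=MuscleParams(
                    f_max=f_max, l_opt=l_opt, l_slack=c0 - x0, alpha_opt=alpha
                ),
                geometry=geom,
                emg_scale=1.0,
            )
        )
    return SubjectLegModel(name="leg", muscles=tuple(muscles),
                           electromechanical_delay_ms=0.0, dofs=(DOF,))


class TestJointMoment:
    def test_inactive_slack_fibers_zero_moment(self):
        leg = one_muscle_leg(-0.05, l_tilde0=0.9)
        assert joint_moment(leg, {"m1": 0.0}, {DOF: 0.0}, DOF) == pytest.approx(0.0)

    def test_single_term_product(self):
        # r = 0.05 everywhere; at optimum with a=1, F = f_max = 1000 -> M = 50
        leg = one_muscle_leg(-0.05, l_tilde0=1.0)
        assert joint_moment(leg, {"m1": 1.0}, {DOF: 0.0}, DOF) == pytest.approx(50.0)

    def test_antagonist_pair_cancels(self):
        leg = one_muscle_leg(-0.05, extra=[(0.05, 0.0)], l_tilde0=1.0)
        m = joint_moment(leg, {"m1": 1.0, "m2": 1.0}, {DOF: 0.0}, DOF)
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_missing_activation_rejected(self):
        leg = one_muscle_leg(-0.05)
        with pytest.raises(KeyError, match="no activation"):
            joint_moment(leg, {}, {DOF: 0.0}, DOF)


class TestMuscleStiffness:
    def test_constant_arm_linear_force_closed_form(self):
        """Constant moment arm + force slope k gives exactly K = r²·k."""
        leg = one_muscle_leg(-0.05, quad=0.0)
        m = leg.muscle("m1")
        for a, th in [(1.0, 0.0), (0.4, 0.2), (0.7, -0.3)]:
            l_mt = 0.40 - 0.05 * th
            k = tendon_force_slope(m.params, a, l_mt)
            got = muscle_stiffness(leg, "m1", a, {DOF: th}, DOF)
            assert got == pytest.approx(0.05**2 * k, rel=1e-12)

    def test_slack_inactive_zero(self):
        leg = one_muscle_leg(-0.05, quad=0.004, l_tilde0=0.9)
        assert muscle_stiffness(leg, "m1", 0.0, {DOF: 0.0}, DOF) == pytest.approx(0.0)

    def test_matches_negative_moment_gradient(self, rng):
        """K equals −∂M/∂θ by central difference on random single-muscle legs."""
        h = 1e-5
        for _ in range(10):
            lin = rng.uniform(-0.06, -0.01)
            quad = rng.uniform(-0.008, 0.008)
            leg = one_muscle_leg(lin, quad, l_tilde0=rng.uniform(0.85, 1.1),
                                 alpha=rng.uniform(0, 0.4))
            a = rng.uniform(0, 1)
            th = rng.uniform(-0.4, 0.4)
            mp = joint_moment(leg, {"m1": a}, {DOF: th + h}, DOF)
            mm = joint_moment(leg, {"m1": a}, {DOF: th - h}, DOF)
            fd = -(mp - mm) / (2 * h)
            got = muscle_stiffness(leg, "m1", a, {DOF: th}, DOF)
            assert got == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestStiffnessSeries:
    def test_constant_inputs_constant_output(self):
        leg = one_muscle_leg(-0.05, quad=0.004)
        s = stiffness_series(
            leg, {"m1": np.full(101, 0.5)}, {DOF: np.full(101, 0.1)}, DOF
        )
        assert np.ptp(s.k_joint) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(s.m_joint) == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_muscles(self, rng):
        leg = one_muscle_leg(-0.05, quad=0.004, extra=[(0.04, 0.005), (-0.02, 0.002)])
        act = {m.name: rng.uniform(0, 1, 101) for m in leg.muscles}
        ang = {DOF: rng.uniform(-0.3, 0.3, 101)}
        s = stiffness_series(leg, act, ang, DOF)
        total = sum(s.k_mus.values())
        np.testing.assert_allclose(s.k_joint, total, rtol=0, atol=0)
        # each contribution equals the standalone single-muscle computation
        for name, km in s.k_mus.items():
            alone = muscle_stiffness(leg, name, act[name], ang, DOF)
            np.testing.assert_allclose(km, alone, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        leg = one_muscle_leg(-0.05)
        with pytest.raises(ValueError, match="101"):
            stiffness_series(leg, {"m1": np.zeros(100)}, {DOF: np.zeros(101)}, DOF)

    def test_passive_stretch_gives_positive_stiffness(self):
        """Inactive muscles on the passive-stretch limb stabilize the joint."""
        leg = one_muscle_leg(-0.05, extra=[(0.05, 0.0)], l_tilde0=1.1)
        s = stiffness_series(
            leg,
            {"m1": np.zeros(101), "m2": np.zeros(101)},
            {DOF: np.zeros(101)},
            DOF,
        )
        assert np.all(s.k_joint > 0)

    def test_activation_does_not_reduce_ascending_limb_stiffness(self):
        leg = one_muscle_leg(-0.05, quad=0.004, l_tilde0=0.9)
        ang = {DOF: np.zeros(101)}
        prev = stiffness_series(leg, {"m1": np.zeros(101)}, ang, DOF).k_joint
        for a in (0.25, 0.5, 1.0):
            cur = stiffness_series(leg, {"m1": np.full(101, a)}, ang, DOF).k_joint
            assert np.all(cur >= prev - 1e-12)
            prev = cur


class TestContributionFractions:
    def test_single_muscle_gets_all(self):
        leg = one_muscle_leg(-0.05, quad=0.004)
        s = stiffness_series(leg, {"m1": np.full(101, 0.5)}, {DOF: np.zeros(101)}, DOF)
        assert contribution_fractions(s) == {"m1": pytest.approx(1.0)}

    def test_symmetric_pair_splits_evenly(self):
        leg = one_muscle_leg(-0.05, extra=[(0.05, 0.0)], l_tilde0=1.0)
        act = {"m1": np.full(101, 0.5), "m2": np.full(101, 0.5)}
        s = stiffness_series(leg, act, {DOF: np.zeros(101)}, DOF)
        frac = contribution_fractions(s)
        assert frac["m1"] == pytest.approx(0.5)
        assert frac["m2"] == pytest.approx(0.5)

    def test_hand_arithmetic_1_1_98(self):
        from ccistiff.joint_stiffness import StiffnessSeries

        k = {
            "a": np.full(101, 1.0),
            "b": np.full(101, 1.0),
            "c": np.full(101, 98.0),
        }
        s = StiffnessSeries(
            dof=DOF, cycle_index=0, k_joint=np.full(101, 100.0), k_mus=k,
            m_joint=np.zeros(101),
        )
        frac = contribution_fractions(s)
        assert frac["a"] == pytest.approx(0.01)
        assert frac["b"] == pytest.approx(0.01)
        assert frac["c"] == pytest.approx(0.98)
        assert frac["a"] < 0.02 and frac["c"] >= 0.02

    def test_all_zero_rejected(self):
        leg = one_muscle_leg(-0.05, l_tilde0=0.9)
        s = stiffness_series(leg, {"m1": np.zeros(101)}, {DOF: np.zeros(101)}, DOF)
        with pytest.raises(ValueError, match="all-zero"):
            contribution_fractions(s)
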