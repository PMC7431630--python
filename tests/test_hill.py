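"""Hill muscle model: frozen direct-evaluation oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinectrl import hill
from spinectrl.actuators import MuscleActuator, MuscleSet, kinematics_from_state
from spinectrl.geometry import PlantState, build_geometry


# frozen values computed by direct evaluation of the published expressions
FV0 = 0.1433 / (0.1074 + np.exp(-1.409 * np.sinh(1.6)))          # 1.004841
FV_SHORT = 0.1433 / (0.1074 + np.exp(1.409 * np.sinh(1.6)))      # 0.005022
FP0 = np.exp(-2.996)                                             # 0.050045


@pytest.mark.parametrize("ratio,expected", [
    (1.0, 1.1),          # 5.1 - 29 + 56 - 41 + 10
    (0.0 + 1e-12, 5.1),  # constant term in the short-length limit
])
def test_force_length_polynomial_values(ratio, expected):
    assert hill.force_length(ratio, 1.0) == pytest.approx(expected, rel=1e-9)


def test_force_length_clamped_to_zero_where_polynomial_negative():
    # the quartic is negative around 1.5 l0; activation must never push
    assert hill.force_length(1.5, 1.0) == 0.0
    r = np.linspace(0.01, 3.0, 500)
    assert np.all(hill.force_length(r, 1.0) >= 0.0)


def test_force_length_rejects_nonpositive_lengths():
    with pytest.raises(ValueError):
        hill.force_length(-1.0, 1.0)
    with pytest.raises(ValueError):
        hill.force_length(1.0, 0.0)


def test_force_velocity_reference_points():
    assert hill.force_velocity(0.0, 1.0) == pytest.approx(FV0, rel=1e-12)
    assert hill.force_velocity(0.0, 1.0) == pytest.approx(1.005, abs=5e-4)
    assert hill.force_velocity(-1.0, 1.0) == pytest.approx(FV_SHORT, rel=1e-12)
    assert hill.force_velocity(-1.0, 1.0) == pytest.approx(0.0050, abs=5e-5)


@given(st.floats(-2.0, 0.35), st.floats(1e-6, 0.35))
@settings(max_examples=200, deadline=None)
def test_force_velocity_strictly_increasing_and_bounded(a, delta):
    # strictly increasing through the physiological band; the sigmoid
    # saturates to its upper bound (0.1433/0.1074) at double precision
    # beyond x ~ 0.75 of the maximum lengthening rate
    assert hill.force_velocity(a, 1.0) < hill.force_velocity(a + delta, 1.0)
    for x in (-5.0, a, 5.0):
        assert 0.0 < hill.force_velocity(x, 1.0) <= hill.FV_MAX


def test_passive_force_reference_points():
    assert hill.passive_force(1.0, 1.0) == pytest.approx(FP0, rel=1e-12)
    assert hill.passive_force(1.0, 1.0) == pytest.approx(0.0500, abs=5e-5)
    # short-length limit and the doubling identity of the exponential
    assert hill.passive_force(1e-9, 1.0) == pytest.approx(np.exp(-10.671), rel=1e-6)
    ratio = hill.passive_force(2.0, 1.0) / hill.passive_force(1.0, 1.0)
    assert ratio == pytest.approx(np.exp(7.675), rel=1e-12)


def test_passive_force_slack_is_zero_at_and_below_rest():
    assert hill.passive_force_slack(1.0, 1.0) == 0.0
    assert hill.passive_force_slack(0.9, 1.0) == 0.0
    assert hill.passive_force_slack(1.1, 1.0) == pytest.approx(
        hill.passive_force(1.1, 1.0) - FP0, rel=1e-12)


@pytest.mark.parametrize("alpha,l,ldot,expected,tol", [
    (0.0, 1.0, 0.0, 800 * FP0, 1e-9),                        # ~40.0 N passive
    (1.0, 1.0, 0.0, 800 * (1.1 * FV0 + FP0), 1e-9),          # ~924 N
    (0.5, 1.0, -10.0, 800 * (0.5 * 1.1 * FV_SHORT + FP0), 1e-9),  # ~42.2 N
])
def test_muscle_force_compositions(alpha, l, ldot, expected, tol):
    # l0 = 1 -> l_dot_max = 10 per second, so ldot = -10 is max shortening
    f = hill.muscle_force(l, ldot, alpha, 1.0, passive="eq")
    assert f == pytest.approx(expected, rel=tol)
    assert expected == pytest.approx({0.0: 40.0, 1.0: 924.0, 0.5: 42.2}[alpha],
                                     abs=0.5)


@given(st.floats(0, 1), st.floats(0, 1), st.floats(0.7, 1.3), st.floats(-5, 5))
@settings(max_examples=100, deadline=None)
def test_muscle_force_affine_increasing_in_activation(a1, a2, l, ldot):
    """F(alpha) is affine and nondecreasing at fixed (l, ldot) - the basis
    of the controller's sign-only Jacobian argument."""
    f = lambda a: hill.muscle_force(l, ldot, a, 1.0, passive="eq")
    mid = f(0.5 * (a1 + a2))
    assert mid == pytest.approx(0.5 * (f(a1) + f(a2)), rel=1e-9, abs=1e-9)
    if a1 < a2:
        assert f(a1) <= f(a2) + 1e-12


def test_muscle_force_derivatives_match_finite_differences():
    l0 = 0.2
    for func, dfunc, pts in [
        (hill.force_length, hill.force_length_derivative, (0.17, 0.2, 0.22)),
        (hill.passive_force, hill.passive_force_derivative, (0.17, 0.2, 0.22)),
        # the slack variant has a kink exactly at the resting length
        (hill.passive_force_slack, hill.passive_force_slack_derivative,
         (0.17, 0.19, 0.22)),
    ]:
        for l in pts:
            h = 1e-7
            fd = (func(l + h, l0) - func(l - h, l0)) / (2 * h)
            assert float(dfunc(l, l0)) == pytest.approx(float(fd), rel=1e-5,
                                                        abs=1e-6)
    for x in (-0.5, 0.0, 0.5):
        h = 1e-7
        fd = (hill.force_velocity(x + h, 1.0) - hill.force_velocity(x - h, 1.0)) / (2 * h)
        assert hill.force_velocity_derivative(x, 1.0) == pytest.approx(
            float(fd), rel=1e-5)


class TestKinematics:
    def test_length_is_euclidean_distance_in_deformed_configuration(self, geometry):
        mset = MuscleSet(geometry, 50.0)
        act = mset.actuators()[-2]          # L1, -Z side
        state = PlantState.zeros(geometry)
        l, ldot, unit = kinematics_from_state(act, state, geometry)
        # origin sits 50 mm lateral of the L1 target -> l = sqrt(190^2 + 50^2)
        assert l == pytest.approx(np.hypot(0.190, 0.050), rel=1e-12)
        assert ldot == 0.0
        assert np.linalg.norm(unit) == pytest.approx(1.0)

    def test_rate_is_projection_of_insertion_velocity(self, geometry):
        mset = MuscleSet(geometry, 50.0)
        act = mset.actuators()[-2]
        state = PlantState.zeros(geometry)
        _, _, unit = kinematics_from_state(act, state, geometry)
        v = 0.037
        state.velocities[3 * act.insertion:3 * act.insertion + 2] = v * unit
        _, ldot, _ = kinematics_from_state(act, state, geometry)
        assert ldot == pytest.approx(v, rel=1e-12)

    def test_coincident_endpoints_rejected(self, geometry):
        act = MuscleActuator("L1", -1, 5, geometry.coords_m[5], 0.1)
        with pytest.raises(ValueError):
            kinematics_from_state(act, PlantState.zeros(geometry), geometry)

    def test_newtons_third_law_pair(self, geometry):
        """One actuator's two nodal force vectors sum to zero exactly."""
        mset = MuscleSet(geometry, 50.0)
        u = np.zeros(3 * geometry.n_nodes)
        v = np.zeros_like(u)
        F, unit, _, _, _ = mset.forces(u, v, np.full(mset.n, 0.3))
        for i in range(mset.n):
            on_insertion = F[i] * unit[i]
            on_origin = -F[i] * unit[i]
            assert np.allclose(on_insertion + on_origin, 0.0)

    def test_alpha_zero_leaves_only_passive_term(self, geometry):
        mset = MuscleSet(geometry, 50.0, passive="eq")
        u = np.zeros(3 * geometry.n_nodes)
        F, _, l, _, _ = mset.forces(u, np.zeros_like(u), np.zeros(mset.n))
        assert np.allclose(F, 800.0 * hill.passive_force(l, mset.l0))
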