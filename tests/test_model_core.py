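"""Unit tests for the planar joint model: kinematics, force laws,
residual statics and the equilibrium sweep."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from ankleuq import (
    ContactPairSpec,
    InvalidParameterError,
    JointModel,
    LigamentSpec,
    LoadSchedule,
    Pose2D,
    RESIDUAL_TOL,
    SingularGeometryError,
    contact_penetration,
    hertz_force_magnitude,
    ligament_force_magnitude,
    ligament_wrench,
    residual,
    solve_equilibrium,
    sweep_loads,
    transform_point,
)
from ankleuq.model import MOMENT_LENGTH_SCALE_M, _CompiledModel, effective_radius


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pose, p, expected",
    [
        (Pose2D(), (3.0, 4.0), (3.0, 4.0)),
        (Pose2D(0, 0, math.pi / 2), (1.0, 0.0), (0.0, 1.0)),
        (Pose2D(1, 2, math.pi), (1.0, 1.0), (0.0, 1.0)),
    ],
)
def test_transform_point_rotates_then_translates(pose, p, expected):
    np.testing.assert_allclose(
        transform_point(pose, p), expected, atol=1e-12
    )


# ---------------------------------------------------------------------------
# element force laws
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "strain, a, b, expected",
    [
        (-0.05, 10.0, 20.0, 0.0),  # slack cable carries no load
        (0.0, 10.0, 20.0, 0.0),
        (0.1, 10.0, 20.0, 10.0 * (math.e**2 - 1.0)),
    ],
)
def test_ligament_force_exponential_law(strain, a, b, expected):
    assert ligament_force_magnitude(strain, a, b) == pytest.approx(
        expected, rel=1e-12
    )


def test_ligament_force_rejects_nonpositive_coefficients():
    with pytest.raises(InvalidParameterError):
        ligament_force_magnitude(0.1, -1.0, 20.0)
    with pytest.raises(InvalidParameterError):
        ligament_force_magnitude(0.1, 10.0, 0.0)


def test_hertz_force_closed_form():
    # independent hand evaluation of (4/3) E* sqrt(R) d^{3/2} in SI units
    e_star = 10.0e6 / (2.0 * (1.0 - 0.4**2))
    expected = (4.0 / 3.0) * e_star * math.sqrt(100e-3) * (0.1e-3) ** 1.5
    assert hertz_force_magnitude(0.1, 10.0, 0.4, 100.0) == pytest.approx(
        expected, rel=1e-12
    )


def test_hertz_force_separation_and_scaling():
    assert hertz_force_magnitude(-0.1, 10.0, 0.4, 100.0) == 0.0
    assert hertz_force_magnitude(0.0, 10.0, 0.4, 100.0) == 0.0
    f1 = hertz_force_magnitude(0.1, 10.0, 0.4, 100.0)
    f2 = hertz_force_magnitude(0.2, 10.0, 0.4, 100.0)
    assert f2 / f1 == pytest.approx(2.0**1.5, rel=1e-12)


def test_hertz_force_invalid_materials():
    with pytest.raises(InvalidParameterError):
        hertz_force_magnitude(0.1, -1.0, 0.4, 100.0)
    with pytest.raises(InvalidParameterError):
        hertz_force_magnitude(0.1, 10.0, 0.6, 100.0)


def test_contact_penetration_center_distance_minus_clearance():
    c = ContactPairSpec(
        center_moving=(0.0, 0.0), center_fixed=(0.0, 0.0),
        radius_inner=20.0, clearance=0.5,
    )
    assert contact_penetration(Pose2D(), c) == pytest.approx(-0.5)
    # onset of contact: centers separated by exactly the clearance
    assert contact_penetration(Pose2D(tx=0.5), c) == pytest.approx(0.0)
    assert contact_penetration(Pose2D(tx=0.7), c) == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# ligament wrench
# ---------------------------------------------------------------------------

def _toy_ligament():
    return LigamentSpec(
        "ATT", attach_moving=(10.0, -5.0), attach_fixed=(2.0, 15.0),
        stiffness_coeff=8.0, shape_coeff=12.0,
    )


def test_ligament_wrench_zero_at_reference():
    force, moment = ligament_wrench(Pose2D(), _toy_ligament())
    np.testing.assert_allclose(force, [0.0, 0.0])
    assert moment == 0.0


def test_ligament_wrench_zero_moment_when_line_passes_reference_point():
    # attachments collinear with the body reference point: no lever arm
    lig = LigamentSpec(
        "ATT", attach_moving=(3.0, 4.0), attach_fixed=(6.0, 8.0),
        stiffness_coeff=8.0, shape_coeff=12.0,
    )
    # stretch the cable by pulling the body straight back along the line
    pose = Pose2D(tx=-0.6, ty=-0.8)
    force, moment = ligament_wrench(pose, lig)
    assert np.linalg.norm(force) > 0.0
    assert moment == pytest.approx(0.0, abs=1e-9)


def test_ligament_wrench_matches_strain_energy_gradient():
    """Wrench equals minus the gradient of the cable's strain energy,
    computed by quadrature of the force law and finite differences."""
    lig = _toy_ligament()
    pf = np.array(lig.attach_fixed)
    l0 = float(np.linalg.norm(pf - np.array(lig.attach_moving)))

    def energy(x):
        pose = Pose2D(*x)
        length = float(
            np.linalg.norm(pf - transform_point(pose, lig.attach_moving))
        )
        if length <= l0:
            return 0.0
        val, _ = quad(
            lambda s: ligament_force_magnitude(
                (s - l0) / l0, lig.stiffness_coeff, lig.shape_coeff
            ),
            l0, length,
        )
        return val

    x = np.array([0.8, 1.1, -0.35])
    force, moment = ligament_wrench(Pose2D(*x), lig)
    h = 1e-6
    grad = np.zeros(3)
    for i in range(3):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad[i] = (energy(xp) - energy(xm)) / (2 * h)
    np.testing.assert_allclose([-grad[0], -grad[1]], force, rtol=1e-6)
    assert -grad[2] == pytest.approx(moment, rel=1e-6)


def test_ligament_wrench_coincident_attachments_is_singular():
    lig = LigamentSpec(
        "ATT", attach_moving=(1.0, 1.0), attach_fixed=(1.0, 1.0),
        stiffness_coeff=8.0, shape_coeff=12.0,
    )
    with pytest.raises(SingularGeometryError):
        ligament_wrench(Pose2D(), lig)


# ---------------------------------------------------------------------------
# residual statics
# ---------------------------------------------------------------------------

def test_residual_zero_when_everything_slack():
    model = JointModel(
        tuple(
            LigamentSpec(n, (x, -10.0), (x, 10.0), 5.0, 10.0)
            for n, x in zip(
                ("ATT", "TC", "PTT", "ATF", "CF", "PTF"),
                (-10.0, -6.0, -2.0, 2.0, 6.0, 10.0),
            )
        ),
        ContactPairSpec((0.0, 0.0), (0.0, 0.1), 20.0, 0.5, 8.0, 0.4),
    )
    np.testing.assert_array_equal(
        residual(Pose2D(), model, 0.0), [0.0, 0.0, 0.0]
    )


def _total_energy_oracle(model, x, m_ext):
    """Independent total potential: quadrature of both force laws minus
    the external-moment work, in N*mm."""
    pose = Pose2D(*x)
    total = 0.0
    for lig in model.ligaments:
        pf = np.array(lig.attach_fixed)
        l0 = float(
            np.linalg.norm(
                pf - transform_point(model.reference_pose, lig.attach_moving)
            )
        )
        length = float(
            np.linalg.norm(pf - transform_point(pose, lig.attach_moving))
        )
        if length > l0:
            val, _ = quad(
                lambda s: ligament_force_magnitude(
                    (s - l0) / l0, lig.stiffness_coeff, lig.shape_coeff
                ),
                l0, length,
            )
            total += val
    depth = contact_penetration(pose, model.contact)
    if depth > 0.0:
        r_eff = effective_radius(model.contact)
        val, _ = quad(
            lambda d: hertz_force_magnitude(
                d, model.contact.youngs_modulus,
                model.contact.poissons_ratio, r_eff,
            ),
            0.0, depth,
        )
        total += val
    return total - m_ext * 1e3 * x[2]


def test_residual_is_negative_energy_gradient(fixture_model, rng):
    """At random poses the residual matches a central finite difference of
    the independently integrated potential energy to 1e-6 relative."""
    for _ in range(10):
        x = rng.uniform([-1.0, -1.0, -0.5], [1.0, 1.0, 0.5])
        m_ext = float(rng.uniform(-5.0, 5.0))
        r = residual(Pose2D(*x), fixture_model, m_ext)
        # undo the moment scaling: third component is Nm / characteristic length
        r_raw = np.array([r[0], r[1], r[2] * MOMENT_LENGTH_SCALE_M * 1e3])
        h = 1e-6
        grad = np.zeros(3)
        for i in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (
                _total_energy_oracle(fixture_model, xp, m_ext)
                - _total_energy_oracle(fixture_model, xm, m_ext)
            ) / (2 * h)
        np.testing.assert_allclose(
            r_raw, -grad, rtol=1e-6, atol=1e-6 * max(1.0, np.abs(r_raw).max())
        )


def test_analytic_jacobian_matches_finite_differences(fixture_model, rng):
    cm = _CompiledModel(fixture_model)
    for _ in range(5):
        x = rng.uniform([-1.0, -1.0, -0.5], [1.0, 1.0, 0.5])
        jac = cm.jacobian(x, 2000.0)
        num = np.zeros((3, 3))
        h = 1e-7
        for i in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num[:, i] = (cm.residual(xp, 2000.0) - cm.residual(xm, 2000.0)) / (
                2 * h
            )
        np.testing.assert_allclose(
            jac, num, rtol=1e-5, atol=1e-6 * max(1.0, np.abs(num).max())
        )


# ---------------------------------------------------------------------------
# equilibrium solve and sweep
# ---------------------------------------------------------------------------

def test_solved_equilibria_satisfy_residual_acceptance(fixture_model):
    state = solve_equilibrium(fixture_model, 0.0, fixture_model.reference_pose)
    assert state.converged
    assert state.residual_sum < RESIDUAL_TOL
    loaded = solve_equilibrium(fixture_model, 3.0, state.pose)
    assert loaded.converged
    assert loaded.residual_sum < RESIDUAL_TOL


def test_zero_load_solve_is_self_consistent(fixture_model):
    state = solve_equilibrium(fixture_model, 0.0, fixture_model.reference_pose)
    again = solve_equilibrium(fixture_model, 0.0, state.pose)
    assert abs(math.degrees(again.pose.theta - state.pose.theta)) < 1e-6


def test_exhausted_iteration_budget_reports_not_converged(fixture_model):
    state = solve_equilibrium(
        fixture_model, 3.0, fixture_model.reference_pose, max_nfev=1
    )
    assert not state.converged


def test_positive_moment_gives_plantarflexion(fixture_model):
    zero = solve_equilibrium(fixture_model, 0.0, fixture_model.reference_pose)
    loaded = solve_equilibrium(fixture_model, 1.0, zero.pose)
    assert loaded.converged
    assert loaded.pose.theta > zero.pose.theta


def test_sweep_zero_only_schedule(fixture_model):
    sw = sweep_loads(fixture_model, LoadSchedule((0.0,)))
    assert sw.angular_displacement == pytest.approx([0.0])
    assert sw.not_passed == 0


def test_sweep_requires_zero_load(fixture_model):
    with pytest.raises(InvalidParameterError):
        sweep_loads(fixture_model, LoadSchedule((1.0, 2.0)))


def test_sweep_is_deterministic(fixture_model, default_sweep):
    again = sweep_loads(fixture_model, LoadSchedule.default())
    np.testing.assert_array_equal(
        again.angular_displacement, default_sweep.angular_displacement
    )
    np.testing.assert_array_equal(
        again.element_forces, default_sweep.element_forces
    )


def test_sweep_order_invariance(fixture_model, default_sweep):
    """The outward march makes the result independent of schedule order."""
    shuffled = LoadSchedule((0.0, 5.0, -5.0, 2.0, -2.0, 4.0, -4.0, 1.0, -1.0,
                             3.0, -3.0))
    sw = sweep_loads(fixture_model, shuffled)
    by_moment = dict(zip(sw.moments, sw.angular_displacement))
    for m, dt in zip(
        default_sweep.moments, default_sweep.angular_displacement
    ):
        assert by_moment[m] == pytest.approx(dt, abs=1e-9)


def test_sweep_displacement_monotone_in_moment(default_sweep):
    assert np.all(np.diff(default_sweep.angular_displacement) >= -1e-9)
    assert default_sweep.not_passed == 0
    # zero displacement at zero load, by definition
    i0 = int(np.flatnonzero(default_sweep.moments == 0.0)[0])
    assert default_sweep.angular_displacement[i0] == 0.0


def test_element_forces_nonnegative(default_sweep):
    assert np.all(default_sweep.element_forces >= 0.0)
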