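"""Hill-type musculotendon mechanics: curves, geometry, dynamics."""
import math

import numpy as np
import pytest

from stancesim import musculotendon as mt


# ---------------------------------------------------------------------------
# parameter tables and kinematics
# ---------------------------------------------------------------------------

def test_parameter_tables_round_trip(mtus):
    assert mtus["SO"].f0 == 3586.0
    assert mtus["SO"].l0 == pytest.approx(0.0490)
    assert mtus["SO"].mass == 0.53
    assert math.degrees(mtus["SO"].alpha0) == pytest.approx(28.30)
    assert math.degrees(mtus["MG"].alpha0) == pytest.approx(9.90)
    assert mtus["MG"].f0 == 1306.0
    assert mtus["LG"].f0 == 606.0
    assert mtus["TA"].f0 == 674.0
    for p in mtus.values():
        assert p.k_pe == 5.0 and p.b_pe == 0.005 and p.strain_pe == 0.50
        assert p.ct == 27.80


@pytest.mark.parametrize("muscle,l_cm,arm_cm", [
    ("SO", 32.30, -4.10), ("MG", 46.40, -4.30),
    ("LG", 45.50, -4.40), ("TA", 30.60, 4.30),
])
def test_neutral_posture_kinematics(mtus, muscle, l_cm, arm_cm):
    p = mtus[muscle]
    assert mt.mtu_length(0.0, p) * 100 == pytest.approx(l_cm)
    assert mt.moment_arm(0.0, p) * 100 == pytest.approx(arm_cm)


@pytest.mark.parametrize("muscle", mt.MUSCLES)
def test_moment_arm_consistent_with_length_gradient(mtus, muscle):
    """Moment arm equals -dL/dtheta (per radian) to within the independent
    least-squares fits' tolerance, across the physiological range."""
    p = mtus[muscle]
    for theta in np.linspace(-15.0, 15.0, 7):
        d = 0.01
        grad = (mt.mtu_length(theta + d, p) - mt.mtu_length(theta - d, p)) \
            / (2 * d) * (180.0 / math.pi)
        arm = mt.moment_arm(theta, p)
        assert arm == pytest.approx(-grad, rel=0.12, abs=5e-4)


def test_muscle_torque_signs_and_linearity(mtus):
    forces = {"SO": 100.0, "MG": 50.0, "LG": 25.0}
    t1 = mt.muscle_torque(0.0, forces, mtus)
    assert t1 < 0                                  # plantar flexion negative
    assert mt.muscle_torque(0.0, {"TA": 100.0}, mtus) > 0
    t2 = mt.muscle_torque(0.0, {k: 2 * v for k, v in forces.items()}, mtus)
    assert t2 == pytest.approx(2 * t1)
    assert mt.muscle_torque(0.0, {m: 0.0 for m in mt.MUSCLES}, mtus) == 0.0
    with pytest.raises(ValueError):
        mt.muscle_torque(0.0, {"SO": -1.0}, mtus)


# ---------------------------------------------------------------------------
# passive elements
# ---------------------------------------------------------------------------

def test_tendon_force_shape(so):
    assert mt.tendon_force(0.80, so) < 1e-3          # slack
    assert float(mt.tendon_force(1.0, so)) == pytest.approx(1.0, abs=0.01)
    # linear region stiffness approaches ct
    d = 1e-4
    slope = (mt.tendon_force(1.05 + d, so) - mt.tendon_force(1.05 - d, so)) \
        / (2 * d)
    assert slope == pytest.approx(so.ct, rel=1e-3)
    # continuity of value and slope across the toe/linear transition
    lr = so.lr
    eps = 1e-5
    f = mt.tendon_force
    local_slope = (f(lr + eps, so) - f(lr - eps, so)) / (2 * eps)
    assert abs(f(lr + eps, so) - f(lr - eps, so)) \
        <= 2 * eps * so.ct + 1e-9                      # no value jump
    s_lo = (f(lr, so) - f(lr - eps, so)) / eps
    s_hi = (f(lr + eps, so) - f(lr, so)) / eps
    assert abs(s_hi - s_lo) < so.ct * 0.01             # no slope jump
    assert 0 < local_slope < so.ct


def test_parallel_passive_force(so):
    assert float(mt.parallel_passive_force(1.0, 0.0, so)) < 0.05
    base = float(mt.parallel_passive_force(1.1, 0.0, so))
    assert float(mt.parallel_passive_force(1.1, 1.0, so)) \
        == pytest.approx(base + so.b_pe)
    assert float(mt.parallel_passive_force(1.1, -1.0, so)) \
        == pytest.approx(base - so.b_pe)
    ls = np.linspace(0.7, 1.5, 30)
    el = mt.parallel_passive_force(ls, 0.0, so)
    assert np.all(np.diff(el) > 0)                   # strictly increasing
    with pytest.raises(ValueError):
        mt.parallel_passive_force(-0.1, 0.0, so)


def test_pinnation_constant_thickness(so):
    assert mt.pinnation(1.0, so) == pytest.approx(so.alpha0)
    assert mt.pinnation(0.8, so) > mt.pinnation(1.2, so)
    with pytest.raises(mt.GeometryError):
        mt.pinnation(0.99 * math.sin(so.alpha0), so)


def test_fibre_geometry_decomposition(so):
    l_mtu = mt.mtu_length(0.0, so)
    lt_norm, alpha = mt.fibre_geometry(l_mtu, 1.0, so)
    assert lt_norm * so.lt0 + 1.0 * so.l0 * math.cos(alpha) \
        == pytest.approx(l_mtu)
    # the printed tendon reference length puts the resting tendon near the
    # toe/linear transition
    assert 0.93 < lt_norm < 1.0


# ---------------------------------------------------------------------------
# contractile elements
# ---------------------------------------------------------------------------

def test_contractile_force_conventions():
    assert float(mt.contractile_force(0.0, 0.0, 1.0, 0.0)) == 0.0
    assert float(mt.contractile_force(1.0, 0.0, 1.0, 0.0)) \
        == pytest.approx(1.0)
    for kind in ("slow", "fast"):
        assert float(mt.force_length(1.0, kind)) == pytest.approx(1.0)
        assert float(mt.force_velocity(1.0, 0.0, kind)) == pytest.approx(1.0)
        ecc = float(mt.force_velocity(1.0, 0.5, kind))
        con = float(mt.force_velocity(1.0, -0.5, kind))
        assert ecc > 1.0 > con > 0.0
        # continuity at V = 0
        assert float(mt.force_velocity(1.0, 1e-9, kind)) \
            == pytest.approx(1.0, abs=1e-6)
    # FL peaks at optimal length
    ls = np.linspace(0.6, 1.5, 40)
    fl = mt.force_length(ls, "slow")
    assert ls[np.argmax(fl)] == pytest.approx(1.0, abs=0.05)
    with pytest.raises(ValueError):
        mt.contractile_force(-0.1, 0.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# fibre dynamics
# ---------------------------------------------------------------------------

def test_fast_accel_matches_reference(so, rng):
    accel = mt.make_fibre_accel(so)
    l_mtu = mt.mtu_length(0.0, so)
    for _ in range(50):
        lf = rng.uniform(0.7, 1.3)
        vf = rng.uniform(-1.0, 1.0)
        a_s = rng.uniform(0, 1)
        a_f = rng.uniform(0, 1 - a_s)
        ref = mt.fibre_acceleration(lf, vf, l_mtu, a_s, a_f, so)
        fast, _ = accel(lf, vf, l_mtu, a_s, a_f)
        assert fast == pytest.approx(ref, rel=1e-12, abs=1e-9)


def test_static_equilibrium_has_zero_acceleration(so):
    l_mtu = mt.mtu_length(0.0, so)
    lf = mt.passive_equilibrium_fibre_length(l_mtu, so)
    acc = mt.fibre_acceleration(lf, 0.0, l_mtu, 0.0, 0.0, so)
    assert abs(acc) < 1e-3 / so.mass_norm * 1e-4


def test_step_load_increase_stretches_fibre(so):
    l_mtu = mt.mtu_length(0.0, so)
    lf = mt.passive_equilibrium_fibre_length(l_mtu, so)
    state = mt.MTUState(lf_norm=lf)
    longer = l_mtu * 1.01                  # step increase in tendon load
    for _ in range(200):
        state = mt.fibre_dynamics_step(state, longer, 0.0, 0.0, so, 5e-5)
    assert state.vf_norm > 0 or state.lf_norm > lf


def test_fibre_step_matches_refined_integration(so):
    l_mtu = mt.mtu_length(0.0, so) * 1.005        # not at equilibrium
    lf0 = mt.passive_equilibrium_fibre_length(mt.mtu_length(0.0, so), so)
    coarse = mt.MTUState(lf_norm=lf0)
    fine = mt.MTUState(lf_norm=lf0)
    dt = 5e-5
    for _ in range(400):
        coarse = mt.fibre_dynamics_step(coarse, l_mtu, 0.1, 0.0, so, dt)
    for _ in range(4000):
        fine = mt.fibre_dynamics_step(fine, l_mtu, 0.1, 0.0, so, dt / 10)
    assert coarse.lf_norm == pytest.approx(fine.lf_norm, abs=1e-5)
    assert coarse.vf_norm == pytest.approx(fine.vf_norm, abs=1e-3)


def test_passive_mtu_dissipates_energy(so):
    """Cyclic length changes of the passive MTU do net positive work on the
    muscle (viscous dissipation)."""
    l0 = mt.mtu_length(0.0, so)
    lf = mt.passive_equilibrium_fibre_length(l0, so)
    state = mt.MTUState(lf_norm=lf)
    dt = 5e-5
    work = 0.0
    f_prev = None
    for i in range(int(1.0 / dt)):
        l_mtu = l0 * (1.0 + 0.002 * math.sin(2 * math.pi * 4.0 * i * dt))
        state = mt.fibre_dynamics_step(state, l_mtu, 0.0, 0.0, so, dt)
        dl = l0 * 0.002 * 2 * math.pi * 4.0 \
            * math.cos(2 * math.pi * 4.0 * i * dt) * dt
        work += state.f_tendon_norm * so.f0 * dl
        f_prev = state.f_tendon_norm
    assert work > 0


# ---------------------------------------------------------------------------
# motor-unit activation
# ---------------------------------------------------------------------------

def test_saturation_properties():
    assert float(mt.saturate(0.0, 0.2)) == 0.0
    u = np.linspace(0, 60, 100)
    a = mt.saturate(u, 0.2)
    assert np.all(np.diff(a) >= 0) and a[-1] <= 1.0
    with pytest.raises(ValueError):
        mt.saturate(-1.0, 0.2)


def test_activation_pool_normalisation_and_types():
    pool = mt.build_activation_pool("SO", {"S": 20, "FR": 3, "FF": 2})
    assert pool.n_units == 25
    a_s, a_f = pool.activations()
    assert a_s == 0.0 and a_f == 0.0                 # no spikes yet
    # a single S unit firing tetanically contributes only to a_slow
    dt = 1e-3
    f_tet = 1.0 / dt * 0  # placeholder; drive unit 0 at its tetanic rate
    rate = 1.0 / 0.05
    for i in range(4000):
        if i % int(1.0 / (rate * dt)) == 0:
            pool.add_spikes([0])
        pool.step(dt)
    a_s, a_f = pool.activations()
    assert a_f == 0.0 and a_s > 0.0
    with pytest.raises(KeyError):
        pool.add_spikes([99])


def test_activation_sums_bounded_at_tetanus():
    """With every unit driven at its tetanic rate the summed activation
    reaches the tetanic plateau (~0.96 of the asymptotic normalisation) and
    never exceeds one."""
    pool = mt.build_activation_pool("MG", {"S": 6, "FR": 3, "FF": 3})
    mu = __import__("stancesim.params", fromlist=["load"]).load("motorunits")
    dt = 5e-4
    rates = np.arctanh(mu["activation"]["saturation_at_tetanic"]) / pool.c
    phases = np.zeros(pool.n_units)
    for i in range(int(3.0 / dt)):
        phases += rates * dt
        fire = np.nonzero(phases >= 1.0)[0]
        phases[fire] -= 1.0
        pool.add_spikes(fire)
        pool.step(dt)
    a_s, a_f = pool.activations()
    assert 0.90 <= a_s + a_f <= 1.0
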