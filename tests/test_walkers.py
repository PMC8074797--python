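"""Walker dynamics: vector fields, Jacobians, collisions, guards, energies.

The oracles here are independent of the generated closed forms: Garcia's
published hip-mass-dominated walker equations for the beta -> 0 limit,
direct angular-momentum accounting from mass positions and velocities for
the collision, finite differences for Jacobians, and tighter-tolerance
re-integration for energy conservation.
"""

import math

import numpy as np
import pytest

from compassgait import _generated as gen
from compassgait.simulate import integrate_step
from compassgait.walkers import (GuardError, PointFeetWalker, WalkerParams,
                                 WalkerState, hamiltonian_to_lagrangian,
                                 lagrangian_to_hamiltonian, make_model)

from conftest import CIRC_PARAMS, POINT_PARAMS, random_states

MODELS = [
    ("point_el", POINT_PARAMS),
    ("point_ham", POINT_PARAMS),
    ("circular", CIRC_PARAMS),
]


# ---------------------------------------------------------------------------
# vector field and state Jacobian
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,params", MODELS)
def test_rate_components_equal_velocities(name, params):
    """The first two derivative components are the (transformed) rates."""
    model = make_model(name, params)
    for s in random_states(model.convention, 10):
        f = model.vector_field(s)
        if name == "point_ham":
            v = hamiltonian_to_lagrangian(s, params)[2:]
            assert f[:2] == pytest.approx(v, abs=1e-12)
        else:
            assert f[:2] == pytest.approx(s[2:], abs=0)
    # zero rates give zero coordinate derivatives
    if name != "point_ham":
        f = model.vector_field([0.1, 0.2, 0.0, 0.0])
        assert f[0] == 0.0 and f[1] == 0.0


def test_simplest_walker_limit():
    """beta -> 0 reduces to Garcia's published simplest-walker equations."""
    params = WalkerParams(beta=1e-6, gamma=0.009)
    model = PointFeetWalker(params)
    for s in random_states("POINT_EL", 20, seed=2):
        th, ph, thd, _ = s
        g = params.gamma
        expected = np.array([
            math.sin(th - g),
            math.sin(th - g) + thd ** 2 * math.sin(ph)
            - math.cos(th - g) * math.sin(ph),
        ])
        f = model.vector_field(s)
        assert f[2:] == pytest.approx(expected, rel=1e-5, abs=1e-6)


def test_hamiltonian_field_is_pushforward_of_lagrangian():
    """ds_HAM/dt equals the chain-rule transform of the EL field."""
    params = POINT_PARAMS
    el = make_model("point_el", params)
    ham = make_model("point_ham", params)
    for s_el in random_states("POINT_EL", 10, seed=3):
        s_ham = lagrangian_to_hamiltonian(s_el, params)
        f_el = el.vector_field(s_el)
        f_ham = ham.vector_field(s_ham)
        # pushforward by finite differences of the transform
        eps = 1e-7
        T = np.empty((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = eps
            T[:, j] = (lagrangian_to_hamiltonian(s_el + e, params)
                       - lagrangian_to_hamiltonian(s_el - e, params)) / (2 * eps)
        assert f_ham == pytest.approx(T @ f_el, rel=1e-5, abs=1e-6)


@pytest.mark.parametrize("name,params", MODELS)
def test_jacobian_matches_finite_differences(name, params):
    """Analytic state Jacobian vs central differences on random states."""
    model = make_model(name, params)
    for s in random_states(model.convention, 100, seed=4):
        J = model.jacobian(s)
        Jfd = np.empty((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1e-6
            Jfd[:, j] = (model.vector_field(s + e)
                         - model.vector_field(s - e)) / 2e-6
        assert np.abs(J - Jfd).max() < 1e-5


def test_point_el_jacobian_block_structure():
    """qdot = v structure: zero upper-left block, identity upper-right."""
    model = make_model("point_el", POINT_PARAMS)
    J = model.jacobian([0.1, 0.3, -0.2, 0.05])
    assert np.abs(J[:2, :2]).max() == 0.0
    assert J[:2, 2:] == pytest.approx(np.eye(2), abs=0)


def test_circular_r0_reduces_to_point_feet():
    """At r = 0 the arc-feet field equals the point-feet one (relabeled)."""
    params_c = WalkerParams(beta=0.03, gamma=0.009, r=0.0)
    circ = make_model("circular", params_c)
    point = make_model("point_el", WalkerParams(beta=0.03, gamma=0.009))
    for s in random_states("POINT_EL", 10, seed=5):
        th, ph, thd, phd = s
        sc = np.array([th - ph, th, thd - phd, thd])
        fc = circ.vector_field(sc)
        fp = point.vector_field(s)
        # phi2 = theta, phi1 = theta - phi
        assert fc[3] == pytest.approx(fp[2], rel=1e-10, abs=1e-12)
        assert fc[2] == pytest.approx(fp[2] - fp[3], rel=1e-10, abs=1e-12)
        Jc = circ.jacobian(sc)
        Jfd = np.empty((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1e-6
            Jfd[:, j] = (circ.vector_field(sc + e)
                         - circ.vector_field(sc - e)) / 2e-6
        assert np.abs(Jc - Jfd).max() < 1e-5


# ---------------------------------------------------------------------------
# collision map
# ---------------------------------------------------------------------------

def _point_mass_kinematics(state, beta):
    """Positions/velocities of all masses of the point-feet walker,
    independent re-derivation from the geometry for momentum oracles."""
    th, ph, thd, phd = state
    hip = np.array([-math.sin(th), math.cos(th)])
    al = th - ph
    swf = hip + np.array([math.sin(al), -math.cos(al)])
    vhip = np.array([-math.cos(th), -math.sin(th)]) * thd
    vswf = vhip + np.array([math.cos(al), math.sin(al)]) * (thd - phd)
    # (position, velocity, mass) for hip, swing foot, stance foot
    return [(hip, vhip, 1.0), (swf, vswf, beta),
            (np.zeros(2), np.zeros(2), beta)]


def _ang_mom(bodies, about):
    L = 0.0
    for pos, vel, mass in bodies:
        r = pos - about
        L += mass * (r[0] * vel[1] - r[1] * vel[0])
    return L


def test_collision_conserves_angular_momentum():
    """System angular momentum about the impact point, and trailing-leg
    angular momentum about the hip, are conserved through the strike."""
    beta = 0.07
    model = PointFeetWalker(WalkerParams(beta=beta, gamma=0.009))
    rng = np.random.default_rng(6)
    for _ in range(20):
        th = rng.uniform(-0.35, -0.06)
        s_pre = np.array([th, 2 * th, rng.uniform(-0.4, -0.05),
                          rng.uniform(-0.2, 0.2)])
        s_post = model.collision_map(s_pre)
        pre = _point_mass_kinematics(s_pre, beta)
        impact = pre[1][0]  # swing foot position
        # post-collision: new stance foot at the impact point
        post = _point_mass_kinematics(s_post, beta)
        post = [(p + impact, v, m) for p, v, m in post]
        assert _ang_mom(pre, impact) == pytest.approx(
            _ang_mom(post, impact), abs=1e-10)
        # trailing leg (old stance foot, mass beta) about the hip
        hip = pre[0][0]
        L_pre = _ang_mom([pre[2]], hip)
        L_post = _ang_mom([post[1]], hip)  # new swing foot = old stance
        assert L_post == pytest.approx(L_pre, abs=1e-10)


def test_collision_zero_velocities_and_angle_relabel():
    model = PointFeetWalker(POINT_PARAMS)
    th = -0.2
    s_pre = np.array([th, 2 * th, 0.0, 0.0])
    s_post = model.collision_map(s_pre)
    assert s_post == pytest.approx([-th, -2 * th, 0.0, 0.0], abs=1e-14)


def test_collision_simplest_walker_law():
    """beta -> 0: the stance-rate ratio approaches cos(2 theta)."""
    model = PointFeetWalker(WalkerParams(beta=1e-6, gamma=0.009))
    th = -0.22
    s_pre = np.array([th, 2 * th, -0.3, 0.1])
    s_post = model.collision_map(s_pre)
    assert s_post[2] / s_pre[2] == pytest.approx(math.cos(2 * th), rel=1e-5)


def test_collision_requires_guard():
    model = PointFeetWalker(POINT_PARAMS)
    with pytest.raises(GuardError):
        model.collision_map([-0.2, -0.1, -0.3, 0.0])  # off the surface
    with pytest.raises(GuardError):
        model.collision_map([0.2, 0.4, -0.3, 0.0])  # guard zero but disarmed


@pytest.mark.parametrize("name,params", MODELS)
def test_collision_jacobian_matches_finite_differences(name, params):
    model = make_model(name, params)
    traj = integrate_step(model, _fixed_state(name, params))
    s_pre = traj.state_pre
    G = model.collision_jacobian(s_pre)
    Gfd = np.empty((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = 1e-7
        Gfd[:, j] = (model.collision_map(s_pre + e, check_guard=False)
                     - model.collision_map(s_pre - e, check_guard=False)) / 2e-7
    assert np.abs(G - Gfd).max() < 1e-6


def _fixed_state(name, params):
    from compassgait import limit_cycle as lc
    from compassgait.walkers import make_model as mk

    if name == "circular":
        guess = lc.cold_start_guess("circular",
                                    WalkerParams(beta=params.beta,
                                                 gamma=params.gamma, r=0.01))
        for r in (0.01, 0.05, 0.09, params.r):
            p = WalkerParams(beta=params.beta, gamma=params.gamma, r=r)
            s = lc.find_period_one(mk("circular", p), guess)
            if s is not None:
                guess = s.fixed_state
        return guess
    sol = lc.find_period_one(mk(name, params),
                             lc.cold_start_guess(name, params))
    return sol.fixed_state


# ---------------------------------------------------------------------------
# guard
# ---------------------------------------------------------------------------

def test_point_scuff_guard_arming():
    """Strike detection is armed only below theta = -0.05 rad."""
    model = PointFeetWalker(POINT_PARAMS)
    assert not model.guard_armed([-0.04, -0.08, -0.3, 0.0])
    assert model.guard_armed([-0.06, -0.12, -0.3, 0.0])


def test_circular_interleg_guard_arming():
    """Swing leg in front and inter-leg angle above 5 degrees."""
    model = make_model("circular", CIRC_PARAMS)
    four_deg = math.radians(4.0)
    six_deg = math.radians(6.0)
    assert not model.guard_armed([four_deg / 2, -four_deg / 2, -0.1, -0.1])
    assert model.guard_armed([six_deg / 2, -six_deg / 2, -0.1, -0.1])
    # swing behind the stance leg: disarmed regardless of the angle
    assert not model.guard_armed([-six_deg / 2, six_deg / 2, -0.1, -0.1])


@pytest.mark.parametrize("name,params", MODELS)
def test_guard_zero_on_strike_surface(name, params):
    model = make_model(name, params)
    if name == "circular":
        s = [0.2, -0.2, -0.1, -0.1]
    else:
        s = [-0.2, -0.4, -0.3, 0.0]
    assert abs(model.guard(s)) < 1e-12


def test_guard_gradient_matches_finite_differences():
    for name, params in MODELS:
        model = make_model(name, params)
        s = np.array([-0.21, -0.42, -0.3, 0.05]) if name != "circular" \
            else np.array([0.2, -0.21, -0.2, -0.2])
        g = model.guard_gradient(s)
        for j in range(4):
            e = np.zeros(4)
            e[j] = 1e-7
            fd = (model.guard(s + e) - model.guard(s - e)) / 2e-7
            assert g[j] == pytest.approx(fd, abs=1e-7)


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def test_transform_round_trip_identity():
    params = POINT_PARAMS
    for s in random_states("POINT_EL", 20, seed=7):
        back = hamiltonian_to_lagrangian(
            lagrangian_to_hamiltonian(s, params), params)
        assert back == pytest.approx(s, abs=1e-12)


def test_zero_velocities_give_zero_momenta():
    s = lagrangian_to_hamiltonian([0.1, 0.3, 0.0, 0.0], POINT_PARAMS)
    assert s[2:] == pytest.approx([0.0, 0.0], abs=0)


def test_momentum_transform_is_nonlinear_in_configuration():
    """p(theta, phi, v) at two configurations with equal rates differ:
    the mass matrix is configuration dependent."""
    v = (-0.25, 0.1)
    p1 = lagrangian_to_hamiltonian([0.1, 0.1, *v], POINT_PARAMS)[2:]
    p2 = lagrangian_to_hamiltonian([0.1, 0.6, *v], POINT_PARAMS)[2:]
    assert np.abs(p1 - p2).max() > 1e-4
    # oracle: mass-matrix difference at the two configurations
    m1 = np.array(gen.pf_mass(0.1, POINT_PARAMS.beta))
    m2 = np.array(gen.pf_mass(0.6, POINT_PARAMS.beta))
    assert np.abs(m1 - m2).max() > 1e-4


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,params", MODELS)
def test_energy_conserved_during_swing(name, params):
    """Passive conservative swing dynamics: drift below 1e-7."""
    model = make_model(name, params)
    traj = integrate_step(model, _fixed_state(name, params))
    E = np.array([model.energy(s) for s in traj.states])
    assert E.max() - E.min() < 1e-7


@pytest.mark.parametrize("name,params", MODELS)
def test_collision_never_increases_kinetic_energy(name, params):
    """The inelastic strike dissipates: KE drops, positions unchanged."""
    model = make_model(name, params)
    traj = integrate_step(model, _fixed_state(name, params))
    ke_pre = model.kinetic_energy(traj.state_pre)
    ke_post = model.kinetic_energy(traj.state_post)
    assert ke_post <= ke_pre + 1e-12


def test_zero_velocity_energy_is_potential_only():
    model = PointFeetWalker(POINT_PARAMS)
    s = [0.15, 0.3, 0.0, 0.0]
    assert model.energy(s) == pytest.approx(model.potential_energy(s))
    assert model.kinetic_energy(s) == pytest.approx(0.0, abs=1e-15)


# ---------------------------------------------------------------------------
# symbolic re-derivation oracle
# ---------------------------------------------------------------------------

def test_generated_point_feet_matches_symbolic_rederivation():
    """The code-generated closed forms agree with a fresh sympy derivation."""
    import sympy as sp

    from compassgait import symbolic

    pf = symbolic.point_feet_exprs()
    TH, PH, THD, PHD, b, g, H = pf["syms"]
    f_l = sp.lambdify((TH, PH, THD, PHD, b, g), list(pf["f"]), "numpy")
    col_l = sp.lambdify((TH, PH, THD, PHD, b), list(pf["col"]), "numpy")
    model = PointFeetWalker(POINT_PARAMS)
    for s in random_states("POINT_EL", 5, seed=8):
        expected = np.array(f_l(*s, POINT_PARAMS.beta, POINT_PARAMS.gamma))
        assert model.vector_field(s) == pytest.approx(expected, rel=1e-12,
                                                      abs=1e-12)
    th = -0.21
    s_pre = np.array([th, 2 * th, -0.3, 0.08])
    expected = np.array(col_l(*s_pre, POINT_PARAMS.beta))
    assert model.collision_map(s_pre) == pytest.approx(expected, abs=1e-12)


def test_walker_state_container():
    s = WalkerState(0.1, 0.2, -0.3, 0.0, "POINT_EL")
    assert np.asarray(s) == pytest.approx([0.1, 0.2, -0.3, 0.0])
    with pytest.raises(ValueError):
        WalkerState(0.1, 0.2, math.inf, 0.0)
    with pytest.raises(ValueError):
        WalkerState(0.1, 0.2, 0.3, 0.0, "BOGUS")
    model = PointFeetWalker(POINT_PARAMS)
    assert model.vector_field(s) == pytest.approx(
        model.vector_field(np.asarray(s)))
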