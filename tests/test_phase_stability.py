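"""Moving frame, divergence measures, foot-strike Jacobian, Rosenstein LDE."""

import numpy as np
import pytest
from scipy.integrate import simpson

from compassgait import phase_stability as ps
from compassgait.simulate import integrate_step
from compassgait.walkers import WalkerParams, make_model

from conftest import TIGHT


# ---------------------------------------------------------------------------
# moving frame
# ---------------------------------------------------------------------------

def test_frame_orthonormal_and_tangent_first(point_el):
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=400)
    for k in range(0, 400, 13):
        U = frame.U[k]
        assert np.abs(U @ U.T - np.eye(4)).max() < 1e-10
        f = model.vector_field(frame.states[k])
        mapped = U @ f
        assert mapped[0] == pytest.approx(np.linalg.norm(f), rel=1e-12)
        assert np.abs(mapped[1:]).max() < 1e-10


def test_frame_rows_vary_continuously(point_el):
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=1000)
    step = np.linalg.norm(np.diff(frame.U, axis=0), axis=(1, 2))
    assert step.max() < 0.05  # no sign flips / pivot jumps


def test_frame_independent_of_sampling_direction(point_el):
    """Frames are pointwise functions of the state: reversing the sample
    order reproduces the same frames."""
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=300)
    rev = ps.moving_frame(model, sol,
                          samples=(frame.times[::-1], frame.states[::-1]))
    assert np.abs(rev.U[::-1] - frame.U).max() < 1e-12


# ---------------------------------------------------------------------------
# transformed and reduced Jacobian
# ---------------------------------------------------------------------------

def test_tangent_perturbations_do_not_leak_into_the_normal_plane(point_el):
    """First column of the transformed Jacobian below the (1,1) entry
    vanishes: a tangent perturbation stays a phase shift."""
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=1000)
    J_bar = ps.transformed_jacobian(model, frame)
    coupling = np.abs(J_bar[:, 1:, 0]).max()
    assert coupling < 1e-6 * np.abs(J_bar).max()


def test_transformed_jacobian_converges_under_refinement(point_el):
    model, sol = point_el
    f1 = ps.moving_frame(model, sol, n_samples=1000)
    f2 = ps.moving_frame(model, sol, n_samples=1999)  # shares every 2nd time
    J1 = ps.transformed_jacobian(model, f1)
    J2 = ps.transformed_jacobian(model, f2)
    assert np.abs(J2[::2] - J1).max() < 1e-6


def test_reduced_jacobian_block_identity(point_el):
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=500)
    J_bar = ps.transformed_jacobian(model, frame)
    J_red = ps.reduced_jacobian(J_bar)
    assert J_red.shape == (500, 3, 3)
    tr_full = np.trace(J_bar, axis1=-2, axis2=-1)
    tr_red = np.trace(J_red, axis1=-2, axis2=-1)
    assert tr_red == pytest.approx(tr_full - J_bar[:, 0, 0], abs=1e-10)


def test_gamma_invariant_under_rotation_of_normal_axes(point_el):
    """Rotating the normal rows by any constant rotation leaves the
    reduced-Jacobian eigenvalues (hence Gamma) unchanged."""
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=300)
    J_red = ps.reduced_jacobian(ps.transformed_jacobian(model, frame))
    rng = np.random.default_rng(11)
    A = rng.normal(size=(3, 3))
    Q = np.linalg.qr(A)[0]
    rotated = ps.MovingFrame(times=frame.times, states=frame.states,
                             U=frame.U.copy())
    rotated.U[:, 1:, :] = Q @ frame.U[:, 1:, :]
    J_red_rot = ps.reduced_jacobian(ps.transformed_jacobian(model, rotated))
    g1 = np.trace(J_red, axis1=-2, axis2=-1)
    g2 = np.trace(J_red_rot, axis1=-2, axis2=-1)
    assert np.abs(g1 - g2).max() < 1e-8
    e1 = np.sort(np.linalg.eigvals(J_red[50]))
    e2 = np.sort(np.linalg.eigvals(J_red_rot[50]))
    assert e2 == pytest.approx(e1, abs=1e-8)


def test_divergence_profile_measures(point_el):
    """Gamma = trace = eigenvalue sum; measures i-iii consistent with the
    quadrature refinement oracle."""
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=1000)
    J_red = ps.reduced_jacobian(ps.transformed_jacobian(model, frame))
    prof = ps.divergence_profile(J_red, frame.times)
    eig_sum = prof.eigs.sum(axis=1).real
    assert np.abs(prof.gamma_t - eig_sum).max() < 1e-8
    assert prof.measure_i == pytest.approx(prof.gamma_t.max())
    assert prof.measure_ii == pytest.approx(prof.gamma_t.min())
    simp = simpson(prof.gamma_t, x=prof.times)
    assert prof.measure_iii == pytest.approx(simp, abs=1e-6)


def test_gamma_scales_inversely_with_time_units(point_el):
    """Stretching time by c divides Gamma by c; the integral is unchanged."""
    model, sol = point_el
    frame = ps.moving_frame(model, sol, n_samples=500)
    J_red = ps.reduced_jacobian(ps.transformed_jacobian(model, frame))
    prof = ps.divergence_profile(J_red, frame.times)
    c = 2.5
    prof_scaled = ps.divergence_profile(J_red / c, frame.times * c)
    assert prof_scaled.measure_i == pytest.approx(prof.measure_i / c)
    assert prof_scaled.measure_iii == pytest.approx(prof.measure_iii,
                                                    rel=1e-12)


# ---------------------------------------------------------------------------
# foot-strike Jacobian
# ---------------------------------------------------------------------------

def test_saltation_identity(point_el, circular):
    """J_FS maps the pre-strike vector field onto the post-strike one."""
    for model, sol in (point_el, circular):
        frame = ps.moving_frame(model, sol, n_samples=300)
        fs = ps.foot_strike_jacobian(model, sol, frame=frame, saltation=True)
        f_pre = model.vector_field(frame.states[-1])
        f_post = model.vector_field(sol.fixed_state)
        assert fs.J_FS @ f_pre == pytest.approx(f_post, abs=1e-6)


def test_foot_strike_jacobian_matches_event_crossing_finite_differences(
        point_el_tight):
    """Brute-force oracle: perturb the pre-strike state, integrate through
    the event, difference the crossing flow map."""
    from scipy.integrate import solve_ivp

    model, sol = point_el_tight
    traj = integrate_step(model, sol.fixed_state, **TIGHT)
    s_pre0 = traj.state_pre
    t_back = 0.05

    def back_state(s_pre):
        # reference point upstream of the strike on the perturbed orbit
        r = solve_ivp(lambda t, y: model.vector_field(y), (0, -t_back),
                      s_pre, rtol=1e-12, atol=1e-12)
        return r.y[:, -1]

    def crossing(s_start, t_fwd):
        # integrate through the strike, then flow for the remaining time
        tr = integrate_step(model, s_start, t_max=5.0, **TIGHT)
        dt_post = t_fwd - tr.strike_time
        r = solve_ivp(lambda t, y: model.vector_field(y), (0, dt_post),
                      tr.state_post, rtol=1e-12, atol=1e-12)
        return r.y[:, -1]

    base = back_state(s_pre0)
    strike_from_base = integrate_step(model, base, t_max=5.0,
                                      **TIGHT).strike_time
    t_fwd = strike_from_base + 0.05
    Jfd = np.empty((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = 1e-6
        Jfd[:, j] = (crossing(base + e, t_fwd)
                     - crossing(base - e, t_fwd)) / 2e-6

    frame = ps.moving_frame(model, sol, n_samples=300, **TIGHT)
    fs = ps.foot_strike_jacobian(model, sol, frame=frame, saltation=True,
                                 **TIGHT)
    # analytic crossing map: flow_post . J_FS . flow_pre linearization
    Phi_pre = _flow_jacobian(model, base, strike_from_base)
    Phi_post = _flow_jacobian(model, sol.fixed_state,
                              t_fwd - strike_from_base)
    analytic = Phi_post @ fs.J_FS @ Phi_pre
    assert np.abs(Jfd - analytic).max() < 1e-4


def _flow_jacobian(model, s0, t):
    from scipy.integrate import solve_ivp

    def rhs(_, y):
        s, Phi = y[:4], y[4:].reshape(4, 4)
        return np.concatenate([model.vector_field(s),
                               (model.jacobian(s) @ Phi).ravel()])

    y0 = np.concatenate([s0, np.eye(4).ravel()])
    r = solve_ivp(rhs, (0, t), y0, rtol=1e-12, atol=1e-12)
    return r.y[4:, -1].reshape(4, 4)


def test_reduced_foot_strike_rank_collapse(point_el, circular):
    """The strike constrains perturbations: the frame-reduced 3x3 strike
    Jacobian has exactly one vanishing eigenvalue.  For point feet the
    collapse is exact (machine zero); for arc feet the residue grows with
    the foot radius but stays below the package vanishing threshold."""
    model, sol = point_el
    fs = ps.foot_strike_jacobian(model, sol, n_samples=300, saltation=True)
    mags = np.sort(np.abs(fs.reduced_eigenvalues))
    assert mags[0] < 1e-8 * mags[-1]
    assert mags[1] > 1e-4 * mags[-1]

    model_c, sol_c = circular
    fs_c = ps.foot_strike_jacobian(model_c, sol_c, n_samples=300,
                                   saltation=True)
    mags_c = np.sort(np.abs(fs_c.reduced_eigenvalues))
    assert mags_c[0] < ps.EPS_VANISH * mags_c[-1]
    assert mags_c[1] > ps.EPS_VANISH * mags_c[-1]


def test_measure_v_trivial_cases():
    assert ps.measure_v([1.0, -1.0, 1j, -1j]) == pytest.approx(1.0)
    lam = 0.3 + 0.4j
    assert ps.measure_v([lam, np.conj(lam)]) == pytest.approx(abs(lam) ** 2)
    assert ps.measure_v([0.5, 1e-12]) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# coordinate-form (in)variance
# ---------------------------------------------------------------------------

def test_measures_iv_and_v_invariant_between_forms(point_el_tight,
                                                   point_ham_tight):
    """The foot-strike divergence and the full-cycle divergence do not
    depend on the choice of state-space form."""
    model_el, sol_el = point_el_tight
    model_ham, sol_ham = point_ham_tight
    ms_el = ps.measure_set(model_el, sol_el, compute_lde=False, **TIGHT)
    ms_ham = ps.measure_set(model_ham, sol_ham, compute_lde=False, **TIGHT)
    assert ms_ham.iv == pytest.approx(ms_el.iv, rel=1e-5)
    assert ms_ham.v == pytest.approx(ms_el.v, rel=1e-5)


def test_measures_i_to_iii_differ_between_forms(point_el_tight,
                                                point_ham_tight):
    """The swing-phase measures are subspace quantities: the nonlinear
    velocity -> momentum transform changes them by far more than the
    numerical tolerance."""
    model_el, sol_el = point_el_tight
    model_ham, sol_ham = point_ham_tight
    ms_el = ps.measure_set(model_el, sol_el, compute_lde=False, **TIGHT)
    ms_ham = ps.measure_set(model_ham, sol_ham, compute_lde=False, **TIGHT)
    for name in ("i", "ii", "iii"):
        a, b = getattr(ms_el, name), getattr(ms_ham, name)
        assert abs(a - b) > 1e-4 * max(abs(a), abs(b)) * 10


def test_full_divergence_rate_identities(point_el_tight, point_ham_tight):
    """trace J = lambda_par + trace J'; and the local divergence rate
    (tangent included) differs between forms (nonlinear transform)."""
    model, sol = point_el_tight
    frame = ps.moving_frame(model, sol, n_samples=500, **TIGHT)
    J_bar = ps.transformed_jacobian(model, frame)
    times, trJ = ps.full_divergence_rate(model, sol,
                                         samples=(frame.times, frame.states))
    tr_bar = np.trace(J_bar, axis1=-2, axis2=-1)
    # similarity invariance of the trace (the dU/dt term is trace-free);
    # interior samples only -- the one-sided derivative stencils at the
    # boundary samples carry a slightly larger discretization floor
    assert np.abs(trJ - tr_bar)[2:-2].max() < 1e-6
    lam_par = J_bar[:, 0, 0]
    J_red = ps.reduced_jacobian(J_bar)
    assert np.abs(tr_bar - lam_par - np.trace(J_red, axis1=-2, axis2=-1)
                  ).max() < 1e-8

    model_h, sol_h = point_ham_tight
    _, trJ_h = ps.full_divergence_rate(model_h, sol_h, n_samples=500,
                                       **TIGHT)
    # well above the ~1e-8 numerical floor: the transform is nonlinear
    assert np.abs(trJ - trJ_h).max() > 1e-3


# ---------------------------------------------------------------------------
# Rosenstein local divergence exponent
# ---------------------------------------------------------------------------

def test_rosenstein_recovers_planted_exponent():
    """Constructed signal: periodic orbit plus epsilon e^{lambda t} u."""
    sps = 50
    t = np.arange(60 * sps) / sps
    base = np.stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t),
                     np.sin(4 * np.pi * t), np.cos(4 * np.pi * t)], axis=1)
    rng = np.random.default_rng(0)
    u = rng.normal(size=4)
    u /= np.linalg.norm(u)
    for lam_true in (0.5, 0.8, 1.2):
        pert = 1e-6 * np.exp(lam_true * t)[:, None] * u
        est, _ = ps.rosenstein_exponent(base + pert, sps)
        assert est == pytest.approx(lam_true, rel=0.05)


def test_lde_zero_for_noise_free_gait(point_el):
    model, sol = point_el
    lam = ps.local_divergence_exponent(model, sol, n_runs=1, n_steps=50,
                                       noise_sd=0.0, seed=1)
    assert abs(lam) < 0.1


def test_lde_deterministic_given_seed(point_el):
    model, sol = point_el
    a = ps.local_divergence_exponent(model, sol, n_runs=2, n_steps=40,
                                     seed=7)
    b = ps.local_divergence_exponent(model, sol, n_runs=2, n_steps=40,
                                     seed=7)
    assert a == b
    c = ps.local_divergence_exponent(model, sol, n_runs=2, n_steps=40,
                                     seed=8)
    assert a != c


def test_lde_positive_under_noise(point_el):
    model, sol = point_el
    lam = ps.local_divergence_exponent(model, sol, n_runs=2, n_steps=60,
                                       seed=2)
    assert lam is not None and lam > 0.2
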