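"""Phase-dependent stability measures of a period-one gait.

The swing-phase analysis linearizes the flow along the periodic solution,
rotates the perturbation dynamics into a moving orthonormal frame whose
first axis is tangent to the orbit, and removes the tangent (phase-shift)
dimension.  The trace of the remaining reduced Jacobian is the
trajectory-normal divergence rate Gamma(t): the instantaneous volume
growth rate of perturbations orthogonal to the orbit.  From it come

* measure i   max of Gamma(t) over the swing,
* measure ii  min of Gamma(t) over the swing,
* measure iii integral of Gamma(t) over the swing (the log of the
  trajectory-normal repulsion rate),
* measure iv  divergence of the reduced foot-strike Jacobian: the product
  of the non-vanishing eigenvalues of the saltation-corrected event
  Jacobian expressed between the pre- and post-strike normal frames,
* measure v   |product of non-vanishing Floquet multipliers| of the full
  cycle,

plus the classical local divergence exponent (short-term maximum
finite-time Lyapunov exponent) estimated with Rosenstein's algorithm from
noisy walking simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _integrate as _core
from .limit_cycle import PeriodOneSolution
from .simulate import FallError, FallReason, integrate_step, walk
from .walkers import WalkerModel

__all__ = [
    "MovingFrame",
    "DivergenceProfile",
    "FootStrikeJacobian",
    "MeasureSet",
    "swing_samples",
    "moving_frame",
    "transformed_jacobian",
    "reduced_jacobian",
    "divergence_profile",
    "foot_strike_jacobian",
    "assembled_monodromy",
    "fundamental_matrix",
    "measure_v",
    "full_divergence_rate",
    "local_divergence_exponent",
    "measure_set",
    "EPS_VANISH",
]

#: Relative threshold below which an eigenvalue counts as vanishing.  The
#: foot strike structurally annihilates one direction of state space; for
#: the point-feet walker the corresponding eigenvalue is zero to machine
#: precision, while the rolling arc-feet collision leaves a residue that
#: grows with the foot radius (up to ~1e-5 near r = 0.5).  1e-4 separates
#: these structural near-zeros from genuine multipliers (>~1e-3 across the
#: study grids) without discontinuities along parameter sweeps.
EPS_VANISH = 1e-4


@dataclass
class MovingFrame:
    """Per-time orthonormal frames along one swing.

    ``U[k]`` is a 4x4 orthonormal matrix whose first row is the normalized
    vector field at ``states[k]``; the remaining rows span the hyperplane
    orthogonal to the orbit.  Rows vary continuously in time.
    """

    times: np.ndarray
    states: np.ndarray
    U: np.ndarray  # (n, 4, 4)


@dataclass
class DivergenceProfile:
    """Time-resolved trajectory-normal divergence rate over a swing."""

    times: np.ndarray
    gamma_t: np.ndarray          # trace of the reduced Jacobian
    eigs: np.ndarray             # (n, 3) eigenvalues of the reduced Jacobian
    measure_i: float             # max Gamma
    measure_ii: float            # min Gamma
    measure_iii: float           # integral of Gamma over the swing


@dataclass
class FootStrikeJacobian:
    """Saltation-corrected event Jacobian of the foot strike.

    ``divergence`` (measure iv) is the magnitude of the product of the
    non-vanishing eigenvalues of the full event Jacobian; that spectrum is
    invariant under the choice of state-space form.  ``J_FS_reduced`` (the
    Jacobian expressed between the pre- and post-strike normal frames with
    the tangent row/column removed) is diagnostic: its rank collapse shows
    the post-impact dimension reduction, but its individual eigenvalues
    depend on the frames.
    """

    J_FS: np.ndarray             # full 4x4, saltation corrected
    J_FS_reduced: np.ndarray     # 3x3, between the normal frames
    divergence: float            # measure iv
    eigenvalues: np.ndarray      # of the full Jacobian
    reduced_eigenvalues: np.ndarray


@dataclass
class MeasureSet:
    """The five phase-dependent measures plus the local divergence exponent."""

    lde: float | None
    i: float
    ii: float
    iii: float
    iv: float
    v: float

    def to_dict(self):
        return {"lde": self.lde, "i": self.i, "ii": self.ii,
                "iii": self.iii, "iv": self.iv, "v": self.v}


def swing_samples(model: WalkerModel, solution: PeriodOneSolution,
                  n_samples=1000, rtol=None, atol=None):
    """Uniform (times, states) sampling of the period-one swing phase.

    Defaults to tighter tolerances (1e-11) than plain walking: the sampled
    states are differentiated downstream (dU/dt), which amplifies dense-
    output noise by the inverse sample spacing.
    """
    rtol = 1e-11 if rtol is None else rtol
    atol = 1e-11 if atol is None else atol
    traj = integrate_step(model, solution.fixed_state, rtol=rtol, atol=atol)
    times = np.linspace(0.0, traj.strike_time, n_samples)
    states = traj.sample(times)
    # pin the exact endpoint states
    states[0] = solution.fixed_state
    states[-1] = traj.state_pre
    return times, states, traj


def moving_frame(model: WalkerModel, solution: PeriodOneSolution,
                 n_samples=1000, rtol=None, atol=None, samples=None):
    """Moving orthonormal frame with the tangent as first axis.

    The normal rows complete the normalized tangent f-hat via the
    Householder reflection that maps an anchor axis onto f-hat.  The anchor
    is the coordinate axis whose tangent component stays farthest from zero
    over the whole swing, so the reflection never degenerates and the frame
    is a smooth pointwise function of the state: rows vary continuously in
    time with no sign flips, and the frame is independent of the sample
    density (unlike a sample-seeded Gram-Schmidt transport).
    """
    if samples is None:
        times, states, _ = swing_samples(model, solution, n_samples,
                                         rtol, atol)
    else:
        times, states = samples
    n = len(times)
    fhat = np.empty((n, 4))
    for k in range(n):
        f = model.vector_field(states[k])
        nf = np.linalg.norm(f)
        if nf < 1e-12:
            raise ValueError("vanishing vector field: degenerate frame")
        fhat[k] = f / nf

    # anchor: axis maximizing the minimal |f-hat| component along the swing
    comp_min = np.min(np.abs(fhat), axis=0)
    a = int(np.argmax(comp_min))
    sigma = np.sign(fhat[0, a]) or 1.0
    if np.min(sigma * fhat[:, a]) < 1e-10:
        raise ValueError("tangent sweeps through every axis: no safe anchor")

    U = np.empty((n, 4, 4))
    ea = np.zeros(4)
    ea[a] = sigma
    normals = [j for j in range(4) if j != a]
    for k in range(n):
        v = fhat[k] - ea
        vv = v @ v
        H = np.eye(4) if vv < 1e-30 else np.eye(4) - 2.0 * np.outer(v, v) / vv
        U[k, 0] = fhat[k]
        for row, j in enumerate(normals, start=1):
            U[k, row] = H[:, j]
    return MovingFrame(times=np.asarray(times), states=np.asarray(states),
                       U=U)


def transformed_jacobian(model: WalkerModel, frame: MovingFrame):
    """Per-time Jacobian in the moving frame: U J U^T + dU/dt U^T.

    dU/dt is obtained by central differences on the sample grid (one-sided
    at the endpoints).  In this frame a tangent initial perturbation does
    not leak into the normal hyperplane: the first column below the (1,1)
    entry vanishes.
    """
    p = model.params
    J = _core.jacobian_batch(model.mid, np.ascontiguousarray(frame.states),
                             p.beta, p.gamma, p.r)
    U = frame.U
    dt = frame.times[1] - frame.times[0]
    dU = _derivative4(U, dt)
    Ut = np.transpose(U, (0, 2, 1))
    return U @ J @ Ut + dU @ Ut


def _derivative4(y, dt):
    """Fourth-order finite-difference time derivative along axis 0.

    Five-point central stencil inside, one-sided fourth-order stencils at
    the four boundary samples; keeps the spurious tangent-normal coupling
    of the transformed Jacobian at the discretization floor.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 6:
        return np.gradient(y, dt, axis=0, edge_order=2)
    d = np.empty_like(y)
    d[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12 * dt)
    fwd = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / (12 * dt)
    for k in (0, 1):
        d[k] = np.tensordot(fwd, y[k:k + 5], axes=(0, 0))
        d[-1 - k] = -np.tensordot(fwd, y[n - 5 - k:n - k][::-1], axes=(0, 0))
    return d


def reduced_jacobian(J_bar):
    """Drop the tangent row and column: the (n, 3, 3) normal-block."""
    J_bar = np.asarray(J_bar)
    return J_bar[..., 1:, 1:]


def divergence_profile(J_prime, times):
    """Trajectory-normal divergence rate and swing measures i-iii.

    Gamma(t) is the trace of the reduced Jacobian (equivalently the sum of
    its eigenvalues); the integral uses the trapezoid rule on the sample
    grid.
    """
    J_prime = np.asarray(J_prime)
    times = np.asarray(times)
    gamma = np.trace(J_prime, axis1=-2, axis2=-1)
    eigs = np.linalg.eigvals(J_prime)
    integral = float(np.trapezoid(gamma, times))
    return DivergenceProfile(
        times=times, gamma_t=gamma, eigs=eigs,
        measure_i=float(np.max(gamma)), measure_ii=float(np.min(gamma)),
        measure_iii=integral)


def _nonvanishing_product(eigs, eps=EPS_VANISH):
    eigs = np.asarray(eigs)
    mags = np.abs(eigs)
    cut = eps * mags.max()
    keep = eigs[mags >= cut]
    return float(np.abs(np.prod(keep))), keep


def foot_strike_jacobian(model: WalkerModel, solution: PeriodOneSolution,
                         frame: MovingFrame | None = None, n_samples=1000,
                         saltation=True, rtol=None, atol=None,
                         eps_vanish=EPS_VANISH):
    """Event Jacobian of the foot strike and its reduced divergence.

    The full Jacobian is the collision-map Jacobian G with the saltation
    (event-timing) correction::

        J_FS = G + (f+ - G f-) grad_h^T / (grad_h . f-)

    so that perturbed trajectories crossing the guard at shifted times are
    mapped consistently: J_FS f- = f+.  Measure iv (the divergence of the
    foot strike) is the magnitude of the product of the non-vanishing
    eigenvalues of J_FS, after eliminating the structurally vanishing
    direction -- the analogue of removing the phase-shift dimension in the
    continuous case.  This spectrum-based construction is invariant under
    the choice of state-space form.  The frame-expressed reduced 3x3 form
    is also returned for rank-collapse diagnostics.  (``saltation=False``
    gives the bare collision-map Jacobian instead; kept for comparison.)
    """
    if frame is None:
        frame = moving_frame(model, solution, n_samples, rtol, atol)
    s_pre = frame.states[-1]
    s_post = solution.fixed_state

    G = model.collision_jacobian(s_pre)
    f_pre = model.vector_field(s_pre)
    f_post = model.vector_field(s_post)
    if saltation:
        grad_h = model.guard_gradient(s_pre)
        denom = grad_h @ f_pre
        if abs(denom) < 1e-10:
            raise ValueError("grazing strike: degenerate saltation")
        J_FS = G + np.outer(f_post - G @ f_pre, grad_h) / denom
    else:
        J_FS = G

    U_pre = frame.U[-1]
    U_post = frame.U[0]
    J_bar = U_post @ J_FS @ U_pre.T
    J_red = J_bar[1:, 1:]
    eigs = np.linalg.eigvals(J_FS)
    div, _ = _nonvanishing_product(eigs, eps_vanish)
    return FootStrikeJacobian(J_FS=J_FS, J_FS_reduced=J_red,
                              divergence=div, eigenvalues=eigs,
                              reduced_eigenvalues=np.linalg.eigvals(J_red))


def fundamental_matrix(model: WalkerModel, solution: PeriodOneSolution,
                       rtol=None, atol=None):
    """Fundamental (state-transition) matrix of the swing linearization.

    Integrates Phi' = J(s(t)) Phi with Phi(0) = I over one swing by the
    variational equations.  Defaults to tighter tolerances than the plain
    trajectory integration because downstream eigenvalue products demand
    more accuracy than the state itself.
    """
    p = model.params
    rtol = 1e-11 if rtol is None else rtol
    atol = 1e-11 if atol is None else atol
    status, y_end, Phi = _core.integrate_variational(
        model.mid, p.beta, p.gamma, p.r,
        np.asarray(solution.fixed_state, dtype=float),
        solution.period, rtol, atol)
    if status != _core.REACHED_TEND:
        raise FallError(FallReason.NUMERIC, "variational integration failed")
    return Phi, y_end


def assembled_monodromy(model: WalkerModel, solution: PeriodOneSolution,
                        rtol=None, atol=None, event_stopped=True):
    """Monodromy assembled from the swing flow and the strike Jacobian.

    Analytic alternative to the finite-difference stride-map Jacobian.
    With ``event_stopped`` (default) the assembly is G S Phi(T), where
    S = I - f- grad_h^T / (grad_h . f-) projects perturbations onto the
    strike surface along the flow: this is the differential of the stride
    map, which annihilates the flow direction (the event eliminates time).
    With ``event_stopped=False`` the assembly is the time-parameterized
    crossing form J_FS Phi(T), which instead carries a unit multiplier
    along the flow; the nontrivial spectrum is the same.
    """
    Phi, s_pre = fundamental_matrix(model, solution, rtol, atol)
    G = model.collision_jacobian(s_pre)
    f_pre = model.vector_field(s_pre)
    f_post = model.vector_field(model.collision_map(s_pre, check_guard=False))
    grad_h = model.guard_gradient(s_pre)
    denom = grad_h @ f_pre
    if event_stopped:
        S = np.eye(4) - np.outer(f_pre, grad_h) / denom
        return G @ S @ Phi
    J_FS = G + np.outer(f_post - G @ f_pre, grad_h) / denom
    return J_FS @ Phi


def measure_v(multipliers, eps_vanish=EPS_VANISH):
    """|product of the non-vanishing Floquet multipliers| (full-cycle
    divergence).  A conjugate pair contributes its squared modulus."""
    prod, _ = _nonvanishing_product(np.asarray(multipliers), eps_vanish)
    return prod


def full_divergence_rate(model: WalkerModel, solution: PeriodOneSolution,
                         n_samples=1000, rtol=None, atol=None, samples=None):
    """trace(J(t)) along the swing, tangent direction included."""
    if samples is None:
        times, states, _ = swing_samples(model, solution, n_samples,
                                         rtol, atol)
    else:
        times, states = samples
    p = model.params
    J = _core.jacobian_batch(model.mid, np.ascontiguousarray(states),
                             p.beta, p.gamma, p.r)
    return np.asarray(times), np.trace(J, axis1=-2, axis2=-1)


# ---------------------------------------------------------------------------
# Rosenstein local divergence exponent
# ---------------------------------------------------------------------------

def rosenstein_exponent(series, samples_per_stride, fit_fraction=0.5,
                        n_neighbors=8, theiler=None):
    """Rosenstein's maximum finite-time Lyapunov exponent, per stride.

    ``series`` is the (n, d) uniformly sampled state time series (used
    directly, no delay embedding).  For every point the nearest neighbor
    outside a temporal exclusion window of one stride is tracked; the slope
    of the mean log-divergence curve over [0, fit_fraction] strides, scaled
    to per-stride units, is returned.
    """
    X = np.asarray(series, dtype=float)
    n = len(X)
    if theiler is None:
        theiler = samples_per_stride
    horizon = max(2, int(round(fit_fraction * samples_per_stride)))
    m = n - horizon
    if m <= theiler + 1:
        raise ValueError("series too short for the requested fit interval")

    tree = cKDTree(X[:m])
    dist, idx = tree.query(X[:m], k=n_neighbors + 1, workers=1)
    base = np.arange(m)
    nn = np.full(m, -1)
    for col in range(1, n_neighbors + 1):
        cand = idx[:, col]
        okmask = (nn < 0) & (np.abs(cand - base) > theiler)
        nn[okmask] = cand[okmask]
    valid = nn >= 0
    i_idx = base[valid]
    j_idx = nn[valid]

    ks = np.arange(horizon + 1)
    logs = np.empty((len(ks),))
    for ki, k in enumerate(ks):
        d = np.linalg.norm(X[i_idx + k] - X[j_idx + k], axis=1)
        logs[ki] = np.mean(np.log(np.maximum(d, 1e-16)))
    # slope in units of 1/sample -> per stride
    slope = np.polyfit(ks, logs, 1)[0]
    return slope * samples_per_stride, (ks, logs)


def local_divergence_exponent(model: WalkerModel,
                              solution: PeriodOneSolution,
                              n_runs=5, n_steps=200, noise_sd=2e-5,
                              seed=0, samples_per_stride=50,
                              fit_fraction=0.5, rtol=None, atol=None,
                              max_redraws=10):
    """Local divergence exponent from noisy walking simulations.

    Per run the walker takes ``n_steps`` steps with independent zero-mean
    Gaussian landing-height noise (sd ``noise_sd``) added at every step;
    the full 4D state series, resampled uniformly with
    ``samples_per_stride`` points per unperturbed stride, feeds
    Rosenstein's algorithm.  The exponent (per stride) is averaged over
    runs.  Runs in which the walker falls are redrawn with fresh seeds;
    persistent falling yields ``None``.
    """
    rng = np.random.default_rng(seed)
    dt = solution.period / samples_per_stride
    exponents = []
    attempts = 0
    while len(exponents) < n_runs and attempts < n_runs + max_redraws:
        attempts += 1
        noise = rng.normal(0.0, noise_sd, size=n_steps) if noise_sd > 0 \
            else np.zeros(n_steps)
        res = walk(model, solution.fixed_state, n_steps=n_steps,
                   rtol=rtol, atol=atol, keep_trajectories=True,
                   ground_noise=noise)
        if not res.survived:
            continue
        chunks = []
        t_offset = 0.0
        grid_next = 0.0
        for traj in res.trajectories:
            t_end = t_offset + traj.strike_time
            ts = np.arange(grid_next, t_end, dt)
            if len(ts):
                chunks.append(traj.sample(ts - t_offset))
                grid_next = ts[-1] + dt
            t_offset = t_end
        series = np.vstack(chunks)
        lam, _ = rosenstein_exponent(series, samples_per_stride,
                                     fit_fraction=fit_fraction)
        exponents.append(lam)
    if len(exponents) < n_runs:
        return None
    return float(np.mean(exponents))


def measure_set(model: WalkerModel, solution: PeriodOneSolution,
                n_samples=1000, lde_kwargs=None, rtol=None, atol=None,
                compute_lde=True, fs_saltation=False):
    """All five phase-dependent measures (and optionally the LDE).

    Measure iv quantifies the volume multiplication of the discrete
    collision event itself, so it defaults to the collision-map Jacobian
    (``fs_saltation=False``); the saltation timing correction mixes in
    swing-flow information that already belongs to the continuous-phase
    measures.  Measure v uses the analytically assembled monodromy (swing
    fundamental matrix times event Jacobian), which agrees with the
    finite-difference Floquet computation but carries less differencing
    noise.
    """
    frame = moving_frame(model, solution, n_samples, rtol, atol)
    J_bar = transformed_jacobian(model, frame)
    prof = divergence_profile(reduced_jacobian(J_bar), frame.times)
    fs = foot_strike_jacobian(model, solution, frame=frame,
                              saltation=fs_saltation, rtol=rtol, atol=atol)
    mono = assembled_monodromy(model, solution, rtol=rtol, atol=atol)
    v = measure_v(np.linalg.eigvals(mono))
    lde = None
    if compute_lde:
        lde = local_divergence_exponent(model, solution, rtol=rtol,
                                        atol=atol, **(lde_kwargs or {}))
    return MeasureSet(lde=lde, i=prof.measure_i, ii=prof.measure_ii,
                      iii=prof.measure_iii, iv=fs.divergence, v=v)
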