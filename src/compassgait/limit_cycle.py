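"""Period-one gait location, Floquet analysis and parameter continuation.

The stride (Poincare) map takes a post-collision state through one swing
phase and the following foot strike.  Period-one gaits are fixed points of
this map, found by Newton-Raphson shooting with a finite-difference map
Jacobian.  The eigenvalues of that Jacobian at the fixed point are the
Floquet multipliers; a gait is stable when every multiplier has modulus
below one.  The collision's rank deficiency makes one multiplier
numerically vanish, and the event (time) elimination means no trivial unit
multiplier arises for this section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import FallError, integrate_step
from .walkers import WalkerModel, WalkerParams, make_model

__all__ = [
    "PeriodOneSolution",
    "stride_map",
    "stride_jacobian",
    "find_period_one",
    "floquet",
    "cold_start_guess",
    "continuation_sweep",
]


@dataclass
class PeriodOneSolution:
    """A located period-one gait.

    ``fixed_state`` is the post-collision state repeating every step,
    ``period`` the step duration, ``monodromy`` the stride-map Jacobian at
    the fixed point and ``multipliers`` its eigenvalues (Floquet
    multipliers), sorted by descending modulus.
    """

    fixed_state: np.ndarray
    period: float
    monodromy: np.ndarray
    multipliers: np.ndarray
    stable: bool
    residual: float
    newton_iterations: int

    @property
    def max_multiplier(self):
        return float(np.max(np.abs(self.multipliers)))

    def to_dict(self):
        return {
            "fixed_state": list(self.fixed_state),
            "period": self.period,
            "multipliers_re": list(self.multipliers.real),
            "multipliers_im": list(self.multipliers.imag),
            "stable": bool(self.stable),
            "residual": self.residual,
            "newton_iterations": self.newton_iterations,
        }


def stride_map(model: WalkerModel, state, rtol=None, atol=None,
               return_period=False):
    """Post-collision state after one full step (swing + collision).

    Raises :class:`~compassgait.simulate.FallError` if the step does not
    complete.
    """
    traj = integrate_step(model, state, rtol=rtol, atol=atol)
    if return_period:
        return traj.state_post, traj.strike_time
    return traj.state_post


def stride_jacobian(model: WalkerModel, state, step=1e-7, rtol=None,
                    atol=None, scheme="central"):
    """Finite-difference Jacobian of the stride map at ``state``."""
    state = np.asarray(state, dtype=float)
    J = np.empty((4, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = step
        sp = stride_map(model, state + e, rtol=rtol, atol=atol)
        if scheme == "central":
            sm = stride_map(model, state - e, rtol=rtol, atol=atol)
            J[:, j] = (sp - sm) / (2 * step)
        else:
            s0 = stride_map(model, state, rtol=rtol, atol=atol)
            J[:, j] = (sp - s0) / step
    return J


def find_period_one(model: WalkerModel, guess, tol=1e-10, max_iter=50,
                    fd_step=1e-7, rtol=None, atol=None):
    """Newton-Raphson shooting for a fixed point of the stride map.

    Returns a :class:`PeriodOneSolution` or ``None`` when the iteration
    diverges, a shot falls, or convergence is not reached.  Unstable gaits
    (including all short-period gaits) are returned with ``stable=False``
    so callers can filter them out.
    """
    s = np.asarray(guess, dtype=float).copy()
    for it in range(1, max_iter + 1):
        try:
            F = stride_map(model, s, rtol=rtol, atol=atol) - s
        except FallError:
            return None
        res = np.max(np.abs(F))
        if res < tol:
            return _finalize(model, s, res, it, rtol, atol)
        # forward-difference Jacobian of F
        J = np.empty((4, 4))
        try:
            for j in range(4):
                e = np.zeros(4)
                e[j] = fd_step
                J[:, j] = (stride_map(model, s + e, rtol=rtol, atol=atol)
                           - s - e - F) / fd_step
        except FallError:
            return None
        try:
            delta = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        # cap the Newton step to keep shots inside the integrable region
        nrm = np.max(np.abs(delta))
        if nrm > 0.3:
            delta *= 0.3 / nrm
        if not np.all(np.isfinite(delta)):
            return None
        s = s + delta
    return None


def _finalize(model, s, res, iters, rtol, atol):
    _, period = stride_map(model, s, rtol=rtol, atol=atol, return_period=True)
    mono = stride_jacobian(model, s, rtol=rtol, atol=atol)
    mult = np.linalg.eigvals(mono)
    mult = mult[np.argsort(-np.abs(mult))]
    stable = bool(np.max(np.abs(mult)) < 1.0)
    return PeriodOneSolution(
        fixed_state=s, period=float(period), monodromy=mono,
        multipliers=mult, stable=stable, residual=float(res),
        newton_iterations=iters)


def floquet(model: WalkerModel, solution: PeriodOneSolution, step=1e-7,
            rtol=None, atol=None):
    """Floquet multipliers from a central-difference stride-map Jacobian.

    Recomputes the monodromy at the stored fixed point; equals
    ``solution.multipliers`` up to finite-difference noise.
    """
    mono = stride_jacobian(model, solution.fixed_state, step=step,
                           rtol=rtol, atol=atol)
    mult = np.linalg.eigvals(mono)
    return mult[np.argsort(-np.abs(mult))]


def cold_start_guess(model_name, params: WalkerParams):
    """Heuristic initial state for Newton shooting.

    Uses the cube-root slope scaling of the long-period passive gait for
    the stance angle and the collision law for the post-strike rates; the
    arc-feet guess reuses the point-feet one in (phi1, phi2) labels.
    """
    g = max(params.gamma, 1e-6)
    th = 0.97 * g ** (1.0 / 3.0)
    thd = -th
    ph = 2 * th
    phd = (1 - np.cos(ph)) * thd
    if model_name == "circular":
        # (phi1, phi2) = (theta - phi, theta); rates accordingly
        return np.array([th - ph, th, thd - phd, thd])
    s = np.array([th, ph, thd, phd])
    if model_name == "point_ham":
        from .walkers import lagrangian_to_hamiltonian

        return lagrangian_to_hamiltonian(s, params)
    return s


def continuation_sweep(model_name, params_list, tol=1e-10, rtol=None,
                       atol=None, warm_start=True):
    """Locate period-one gaits along an ordered parameter list.

    Each successful solution seeds the next combination's Newton shot
    (continuation); cold-start heuristics are used at the start and after
    failures.  Returns a list of ``PeriodOneSolution`` or ``None`` aligned
    with ``params_list``.
    """
    out = []
    prev = None
    for params in params_list:
        model = make_model(model_name, params)
        guesses = []
        if warm_start and prev is not None:
            guesses.append(prev)
        guesses.append(cold_start_guess(model_name, params))
        sol = None
        for guess in guesses:
            sol = find_period_one(model, guess, tol=tol, rtol=rtol, atol=atol)
            if sol is not None:
                break
        out.append(sol)
        if sol is not None:
            prev = sol.fixed_state
    return out
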