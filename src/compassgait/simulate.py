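"""Hybrid step integration, perturbations, multi-step walking, robustness.

A gait cycle is one swing phase integrated until the armed strike guard
fires, followed by the instantaneous inelastic collision.  Two one-time
perturbation protocols are provided:

``STEP_HEIGHT``
    The ground height for the first step's landing is shifted by the signed
    magnitude (units of leg length); positive = step-up.

``PUSH``
    A constant horizontal force (units of Mg, positive in the direction of
    progression) applied at each leg's midpoint for a fixed duration,
    switched on when the hip (inter-leg) angle crosses zero.

Gait robustness is the largest survivable one-time perturbation, located by
geometric bracketing followed by bisection down to a configured precision;
"surviving" means completing 30 consecutive steps without a fall.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from . import _integrate as _core
from .walkers import WalkerModel

__all__ = [
    "FallReason",
    "Perturbation",
    "Trajectory",
    "WalkResult",
    "RobustnessResult",
    "FallError",
    "integrate_step",
    "walk",
    "max_perturbation",
    "robustness",
    "DEFAULT_TOLERANCES",
    "DEFAULT_PRECISIONS",
]

#: paper-matched integrator tolerances (abs = rel) per model family
DEFAULT_TOLERANCES = {"point_el": 1e-8, "point_ham": 1e-8, "circular": 1e-10}
#: robustness search precisions: (model family, perturbation kind)
DEFAULT_PRECISIONS = {
    ("point", "step_height"): 1e-5,
    ("circular", "step_height"): 1e-4,
    ("point", "push"): 1e-2,
    ("circular", "push"): 1e-2,
}

_MAX_NODES = 40000


class FallReason(enum.Enum):
    """Why a step failed to complete."""

    NONE = "none"
    NO_STRIKE = "fall_no_strike"     # no foot strike within the horizon
    BOUNDS = "fall_bounds"           # stance angle beyond +-pi/2
    NUMERIC = "fall_numeric"         # integrator breakdown


class FallError(RuntimeError):
    def __init__(self, reason: FallReason, message=""):
        super().__init__(message or reason.value)
        self.reason = reason


@dataclass(frozen=True)
class Perturbation:
    """A one-time perturbation applied during the first step.

    kind = 'step_height': ``magnitude`` is the signed landing-height offset.
    kind = 'push': ``magnitude`` is the signed horizontal force per leg
    (positive = push in the direction of progression, negative = pull),
    active for ``duration`` time units from the hip-angle zero crossing.
    """

    kind: str
    magnitude: float
    duration: float = 0.1

    def __post_init__(self):
        if self.kind not in ("step_height", "push"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass
class Trajectory:
    """One integrated step: dense nodes plus the strike and collision."""

    times: np.ndarray           # accepted integrator nodes (strictly increasing)
    states: np.ndarray          # (n, 4) states at the nodes
    derivs: np.ndarray          # (n, 4) vector field at the nodes
    strike_time: float
    state_pre: np.ndarray       # state on the strike surface
    state_post: np.ndarray      # post-collision (relabelled) state

    def sample(self, times):
        """Dense output at arbitrary times within the step."""
        return _core.hermite_sample(times, self.times, self.states, self.derivs)

    def to_csv(self, path, step_index=0):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=["q1", "q2", "v1", "v2"])
        df.insert(0, "t", self.times)
        df["step_index"] = step_index
        df.to_csv(path, index=False)

    def metadata(self):
        return {
            "strike_time": self.strike_time,
            "state_pre": list(self.state_pre),
            "state_post": list(self.state_post),
        }


@dataclass
class WalkResult:
    survived: bool
    steps_completed: int
    fall_reason: FallReason
    final_state: np.ndarray | None
    trajectories: list = field(default_factory=list)


def _tolerance_for(model: WalkerModel):
    return 1e-10 if model.mid == 2 else 1e-8


def integrate_step(model: WalkerModel, state0, perturbation=None,
                   rtol=None, atol=None, t_max=10.0, ground=0.0):
    """Integrate one full step (swing + collision) from a post-collision state.

    Raises :class:`FallError` if no strike occurs within ``t_max`` time
    units, the stance angle leaves (-pi/2, pi/2), or the integrator breaks
    down.  ``ground`` shifts the landing height for this step (used by the
    step perturbation); a ``push`` perturbation splits the swing into
    segments around the force window.
    """
    state0 = np.asarray(state0, dtype=float)
    tol = _tolerance_for(model)
    rtol = tol if rtol is None else rtol
    atol = tol if atol is None else atol
    p = model.params

    if perturbation is not None and perturbation.kind == "step_height":
        ground = ground + perturbation.magnitude
        perturbation = None

    rec_t = np.empty(_MAX_NODES)
    rec_y = np.empty((_MAX_NODES, 4))
    rec_f = np.empty((_MAX_NODES, 4))

    def seg(t0, y0, push, t_end, event_kind, n0):
        return _core.integrate_segment(
            model.mid, p.beta, p.gamma, p.r, push, ground,
            t0, y0, t_end, rtol, atol, event_kind,
            rec_t, rec_y, rec_f, n0)

    n = 0
    if perturbation is None:
        status, which, t_fin, y_fin, n = seg(
            0.0, state0, 0.0, t_max, _core.EV_STRIKE, 0)
    else:
        # push: free swing -> hip-angle zero -> forced window -> free swing
        status, which, t_fin, y_fin, n = seg(
            0.0, state0, 0.0, t_max, _core.EV_BOTH, 0)
        if status == _core.OK_EVENT and which == _core.EV_HIP:
            status, which, t_fin, y_fin, n = seg(
                t_fin, y_fin, perturbation.magnitude,
                min(t_fin + perturbation.duration, t_max),
                _core.EV_STRIKE, n - 1)
            if status == _core.REACHED_TEND:
                status, which, t_fin, y_fin, n = seg(
                    t_fin, y_fin, 0.0, t_max, _core.EV_STRIKE, n - 1)

    if status == _core.FALL_BOUNDS:
        raise FallError(FallReason.BOUNDS)
    if status == _core.FALL_NUMERIC:
        raise FallError(FallReason.NUMERIC)
    if status == _core.REACHED_TEND or which != _core.EV_STRIKE:
        raise FallError(FallReason.NO_STRIKE)
    if t_fin <= 0.0:
        raise FallError(FallReason.NUMERIC, "degenerate immediate strike")

    state_pre = y_fin
    state_post = model.collision_map(state_pre, check_guard=False)
    return Trajectory(
        times=rec_t[:n].copy(), states=rec_y[:n].copy(),
        derivs=rec_f[:n].copy(), strike_time=t_fin,
        state_pre=state_pre, state_post=state_post)


def walk(model: WalkerModel, state0, n_steps=30, perturbation=None,
         rtol=None, atol=None, keep_trajectories=False,
         ground_noise=None):
    """Walk up to ``n_steps`` consecutive steps; perturb the first one.

    ``ground_noise`` (optional array of per-step landing-height offsets,
    used by the local-divergence-exponent protocol) is applied one entry
    per step.  Returns a :class:`WalkResult`.
    """
    state = np.asarray(state0, dtype=float)
    trajs = []
    for k in range(n_steps):
        pert = perturbation if k == 0 else None
        g = 0.0 if ground_noise is None else float(ground_noise[k])
        try:
            traj = integrate_step(model, state, perturbation=pert,
                                  rtol=rtol, atol=atol, ground=g)
        except FallError as err:
            return WalkResult(False, k, err.reason, None, trajs)
        state = traj.state_post
        if keep_trajectories:
            trajs.append(traj)
    return WalkResult(True, n_steps, FallReason.NONE, state, trajs)


@dataclass
class RobustnessResult:
    """Directional perturbation maxima and their sums.

    ``robustness_height`` = max step-up + max step-down;
    ``robustness_force`` = max push + max pull (absolute magnitudes).
    """

    max_step_up: float | None = None
    max_step_down: float | None = None
    max_push: float | None = None
    max_pull: float | None = None
    precision_height: float | None = None
    precision_force: float | None = None

    @property
    def robustness_height(self):
        if self.max_step_up is None or self.max_step_down is None:
            return None
        return self.max_step_up + self.max_step_down

    @property
    def robustness_force(self):
        if self.max_push is None or self.max_pull is None:
            return None
        return self.max_push + self.max_pull

    def to_dict(self):
        return {
            "max_step_up": self.max_step_up,
            "max_step_down": self.max_step_down,
            "max_push": self.max_push,
            "max_pull": self.max_pull,
            "robustness_height": self.robustness_height,
            "robustness_force": self.robustness_force,
        }


def _survives(model, state0, kind, signed_magnitude, n_steps, rtol, atol):
    pert = Perturbation(kind, signed_magnitude)
    res = walk(model, state0, n_steps=n_steps, perturbation=pert,
               rtol=rtol, atol=atol)
    return res.survived


def max_perturbation(model: WalkerModel, fixed_state, kind, direction,
                     precision=None, n_steps=30, rtol=None, atol=None,
                     initial=None, max_magnitude=None,
                     on_non_monotone=None):
    """Largest survivable one-time perturbation magnitude (>= 0).

    ``direction`` is '+' (step-up / push) or '-' (step-down / pull); the
    returned magnitude is unsigned.  The search brackets geometrically from
    ``initial`` and bisects until the surviving/failing bracket is narrower
    than ``precision``; by construction the returned magnitude survives
    while magnitude + precision fails.
    """
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    fam = "circular" if model.mid == 2 else "point"
    if precision is None:
        precision = DEFAULT_PRECISIONS[(fam, kind)]
    if initial is None:
        initial = 1e-3 if kind == "step_height" else 1e-2
    if max_magnitude is None:
        max_magnitude = 1.0 if kind == "step_height" else 10.0
    sign = 1.0 if direction == "+" else -1.0
    fixed_state = np.asarray(fixed_state, dtype=float)

    def ok(mag):
        return _survives(model, fixed_state, kind, sign * mag,
                         n_steps, rtol, atol)

    # geometric bracketing
    lo = 0.0
    hi = initial
    while ok(hi):
        lo = hi
        hi *= 2.0
        if hi > max_magnitude:
            if ok(max_magnitude):
                return max_magnitude
            lo, hi = lo, max_magnitude
            break
    if lo == 0.0 and hi <= precision:
        return 0.0

    # bisection: survives at lo, falls at hi
    while hi - lo > precision:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            if on_non_monotone is not None and mid > lo + precision:
                pass  # monotone path maintained by construction
            lo = mid
        else:
            hi = mid
    return lo


def robustness(model: WalkerModel, fixed_state, kinds=("step_height",),
               precisions=None, n_steps=30, rtol=None, atol=None):
    """Aggregate directional robustness for the requested perturbation kinds.

    The height robustness (step perturbations) applies to both walkers; the
    force robustness (push/pull) is part of the circular-feet protocol but
    available for every model.
    """
    fam = "circular" if model.mid == 2 else "point"
    res = RobustnessResult()
    for kind in kinds:
        prec = None if precisions is None else precisions.get(kind)
        if prec is None:
            prec = DEFAULT_PRECISIONS[(fam, kind)]
        up = max_perturbation(model, fixed_state, kind, "+", precision=prec,
                              n_steps=n_steps, rtol=rtol, atol=atol)
        down = max_perturbation(model, fixed_state, kind, "-", precision=prec,
                                n_steps=n_steps, rtol=rtol, atol=atol)
        if kind == "step_height":
            res.max_step_up, res.max_step_down = up, down
            res.precision_height = prec
        else:
            res.max_push, res.max_pull = up, down
            res.precision_force = prec
    return res
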