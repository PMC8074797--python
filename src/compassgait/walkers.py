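"""Walker models: vector fields, Jacobians, collision maps, guards, energies.

Three dynamical formulations of the passive compass walker are provided:

``PointFeetWalker``
    Point-feet biped in Euler-Lagrange form, state (theta, phi, thetadot,
    phidot): stance-leg angle from the slope normal, inter-leg angle, and
    their rates.  Hip point mass 1, foot point masses ``beta``; massless
    legs; slope ``gamma``; nondimensional units (l = g = 1).

``PointFeetHamiltonianWalker``
    The same mechanical system in Hamiltonian canonical form, state
    (theta, phi, p_theta, p_phi) with conjugate momenta p = M(q) qdot.
    Because the mass matrix is configuration dependent the velocity ->
    momentum transform is nonlinear in the state.

``CircularFeetWalker``
    Arc-feet biped with rolling stance contact and gravity tilted by the
    slope, state (phi1, phi2, phi1dot, phi2dot): swing- and stance-leg
    angles from the ground normal.  Foot radius ``r`` (arc centre on the
    leg axis, 1 - r from the hip).  At r = 0 it coincides with the
    point-feet walker.

All closed-form expressions live in :mod:`compassgait._generated` and are
derived (and re-derivable) by :mod:`compassgait.symbolic`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _generated as _g

__all__ = [
    "WalkerParams",
    "WalkerState",
    "WalkerModel",
    "PointFeetWalker",
    "PointFeetHamiltonianWalker",
    "CircularFeetWalker",
    "make_model",
    "lagrangian_to_hamiltonian",
    "hamiltonian_to_lagrangian",
    "GuardError",
    "NonIntegrableStateError",
    "SCUFF_THETA_MAX",
    "MIN_INTERLEG_ANGLE",
]

#: Point-feet scuff guard: strike detection armed only for theta below this.
SCUFF_THETA_MAX = -0.05
#: Arc-feet scuff guard: inter-leg angle (swing in front) must exceed 5 deg.
MIN_INTERLEG_ANGLE = math.radians(5.0)

_CONVENTIONS = ("POINT_EL", "POINT_HAM", "CIRCULAR")


class GuardError(ValueError):
    """A collision was requested at a state not on the strike surface."""


class NonIntegrableStateError(ValueError):
    """Mass matrix (numerically) singular at the requested configuration."""


@dataclass(frozen=True)
class WalkerParams:
    """Configuration parameters of a walker.

    Parameters
    ----------
    beta : float
        Foot-to-hip mass ratio m/M (dimensionless, > 0).
    gamma : float
        Slope angle in radians (>= 0).
    r : float
        Foot radius as a fraction of leg length, only meaningful for the
        circular-feet model (0 <= r < 1).
    """

    beta: float = 0.01
    gamma: float = 0.009
    r: float = 0.0

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not 0 <= self.r < 1:
            raise ValueError(f"r must be in [0, 1), got {self.r}")


@dataclass(frozen=True)
class WalkerState:
    """A labelled 4-component walker state.

    ``convention`` is one of ``POINT_EL`` (theta, phi, thetadot, phidot),
    ``POINT_HAM`` (theta, phi, p_theta, p_phi) or ``CIRCULAR`` (phi1, phi2,
    phi1dot, phi2dot).  Instances interoperate with numpy via ``__array__``;
    all model methods equally accept plain length-4 arrays.
    """

    q1: float
    q2: float
    v1: float
    v2: float
    convention: str = "POINT_EL"

    def __post_init__(self):
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if not all(map(math.isfinite, (self.q1, self.q2, self.v1, self.v2))):
            raise ValueError("state components must be finite")

    def __array__(self, dtype=None, copy=None):
        return np.array([self.q1, self.q2, self.v1, self.v2], dtype=dtype or float)

    @classmethod
    def from_array(cls, s, convention="POINT_EL"):
        s = np.asarray(s, dtype=float)
        return cls(s[0], s[1], s[2], s[3], convention)


def _asstate(s):
    s = np.asarray(s, dtype=float)
    if s.shape != (4,):
        raise ValueError(f"expected a 4-component state, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise NonIntegrableStateError("non-finite state")
    return s


class WalkerModel:
    """Common interface of the three walker formulations."""

    mid: int  # integer model id used by the compiled integrator
    convention: str

    def __init__(self, params: WalkerParams):
        self.params = params

    # -- interface -------------------------------------------------------
    def vector_field(self, s):
        """Time derivative ds/dt of the swing-phase dynamics."""
        raise NotImplementedError

    def jacobian(self, s):
        """State Jacobian d(vector_field)/ds, shape (4, 4)."""
        raise NotImplementedError

    def collision_map(self, s, check_guard=True, ground=0.0, guard_tol=1e-8):
        """Post-collision state after an inelastic foot strike.

        Legs are relabelled so the result is again a valid swing-phase
        state.  The velocity part of the map is linear in the pre-strike
        velocities.  With ``check_guard`` the state must lie on the strike
        surface (guard zero to ``guard_tol`` and the scuff guard armed).
        """
        raise NotImplementedError

    def collision_jacobian(self, s):
        """Jacobian of :meth:`collision_map` w.r.t. the pre-strike state."""
        raise NotImplementedError

    def guard(self, s, ground=0.0):
        """Signed swing-foot clearance; the armed zero crossing from above
        marks foot strike.  ``ground`` shifts the landing height."""
        raise NotImplementedError

    def guard_gradient(self, s):
        """State gradient of :meth:`guard` (independent of ``ground``)."""
        raise NotImplementedError

    def guard_armed(self, s):
        """Whether strike detection is armed (scuff guard satisfied)."""
        raise NotImplementedError

    def energy(self, s):
        """Total mechanical energy (kinetic + tilted-frame potential)."""
        raise NotImplementedError

    def kinetic_energy(self, s):
        raise NotImplementedError

    def push_vector_field_term(self, s, force):
        """Additive vector-field contribution of a horizontal force of
        magnitude ``force`` (units of Mg) applied at each leg's midpoint."""
        raise NotImplementedError

    # -- shared helpers --------------------------------------------------
    def _check_guard(self, s, ground, guard_tol):
        h = self.guard(s, ground)
        if abs(h) > guard_tol:
            raise GuardError(
                f"state not on the strike surface: guard = {h:.3e}"
            )
        if not self.guard_armed(s):
            raise GuardError("strike guard not armed at this state")


class PointFeetWalker(WalkerModel):
    """Point-feet compass walker, Euler-Lagrange form (theta, phi, rates)."""

    mid = 0
    convention = "POINT_EL"

    def vector_field(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(_g.pf_f(s[0], s[1], s[2], s[3], p.beta, p.gamma))

    def jacobian(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(
            _g.pf_jac(s[0], s[1], s[2], s[3], p.beta, p.gamma)
        ).reshape(4, 4)

    def mass_matrix(self, s):
        s = _asstate(s)
        m11, m12, m22 = _g.pf_mass(s[1], self.params.beta)
        M = np.array([[m11, m12], [m12, m22]])
        if abs(np.linalg.det(M)) < 1e-14:
            raise NonIntegrableStateError("singular mass matrix")
        return M

    def collision_map(self, s, check_guard=True, ground=0.0, guard_tol=1e-8):
        s = _asstate(s)
        if check_guard:
            self._check_guard(s, ground, guard_tol)
        return np.array(_g.pf_col(s[0], s[1], s[2], s[3], self.params.beta))

    def collision_jacobian(self, s):
        s = _asstate(s)
        return np.array(
            _g.pf_coljac(s[0], s[1], s[2], s[3], self.params.beta)
        ).reshape(4, 4)

    def guard(self, s, ground=0.0):
        s = _asstate(s)
        return _g.pf_guard(s[0], s[1], ground)

    def guard_gradient(self, s):
        s = _asstate(s)
        return np.array(_g.pf_dguard(s[0], s[1]))

    def guard_armed(self, s):
        s = _asstate(s)
        return s[0] < SCUFF_THETA_MAX

    def kinetic_energy(self, s):
        s = _asstate(s)
        return _g.pf_ke(s[0], s[1], s[2], s[3], self.params.beta)

    def potential_energy(self, s):
        s = _asstate(s)
        p = self.params
        return _g.pf_pot(s[0], s[1], p.beta, p.gamma)

    def energy(self, s):
        return self.kinetic_energy(s) + self.potential_energy(s)

    def push_vector_field_term(self, s, force):
        s = _asstate(s)
        Q = force * np.array(_g.pf_qpush(s[0], s[1]))
        acc = np.linalg.solve(self.mass_matrix(s), Q)
        return np.array([0.0, 0.0, acc[0], acc[1]])


class PointFeetHamiltonianWalker(WalkerModel):
    """Point-feet compass walker in Hamiltonian canonical form."""

    mid = 1
    convention = "POINT_HAM"

    def vector_field(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(_g.hm_f(s[0], s[1], s[2], s[3], p.beta, p.gamma))

    def jacobian(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(
            _g.hm_jac(s[0], s[1], s[2], s[3], p.beta, p.gamma)
        ).reshape(4, 4)

    def _el(self):
        return PointFeetWalker(self.params)

    def collision_map(self, s, check_guard=True, ground=0.0, guard_tol=1e-8):
        s = _asstate(s)
        if check_guard:
            self._check_guard(s, ground, guard_tol)
        el = self._el()
        s_el = hamiltonian_to_lagrangian(s, self.params)
        post_el = el.collision_map(s_el, check_guard=False)
        return lagrangian_to_hamiltonian(post_el, self.params)

    def collision_jacobian(self, s):
        # chain rule through the (nonlinear) momentum transform evaluated
        # at the pre- and post-strike configurations
        s = _asstate(s)
        el = self._el()
        s_el = hamiltonian_to_lagrangian(s, self.params)
        post_el = el.collision_map(s_el, check_guard=False)
        G = el.collision_jacobian(s_el)
        T_pre = _transform_jacobian(s_el, self.params)
        T_post = _transform_jacobian(post_el, self.params)
        return T_post @ G @ np.linalg.inv(T_pre)

    def guard(self, s, ground=0.0):
        s = _asstate(s)
        return _g.pf_guard(s[0], s[1], ground)

    def guard_gradient(self, s):
        s = _asstate(s)
        return np.array(_g.pf_dguard(s[0], s[1]))

    def guard_armed(self, s):
        s = _asstate(s)
        return s[0] < SCUFF_THETA_MAX

    def energy(self, s):
        s = _asstate(s)
        p = self.params
        return _g.hm_energy(s[0], s[1], s[2], s[3], p.beta, p.gamma)

    def kinetic_energy(self, s):
        s = _asstate(s)
        p = self.params
        return self.energy(s) - _g.pf_pot(s[0], s[1], p.beta, p.gamma)

    def push_vector_field_term(self, s, force):
        # generalized forces enter the momentum equations directly
        s = _asstate(s)
        Q = force * np.array(_g.pf_qpush(s[0], s[1]))
        return np.array([0.0, 0.0, Q[0], Q[1]])


class CircularFeetWalker(WalkerModel):
    """Arc-feet compass walker with rolling stance contact."""

    mid = 2
    convention = "CIRCULAR"

    def vector_field(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(_g.cf_f(s[0], s[1], s[2], s[3], p.beta, p.gamma, p.r))

    def jacobian(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(
            _g.cf_jac(s[0], s[1], s[2], s[3], p.beta, p.gamma, p.r)
        ).reshape(4, 4)

    def mass_matrix(self, s):
        s = _asstate(s)
        p = self.params
        m11, m12, m22 = _g.cf_mass(s[0], s[1], p.beta, p.r)
        M = np.array([[m11, m12], [m12, m22]])
        if abs(np.linalg.det(M)) < 1e-14:
            raise NonIntegrableStateError("singular mass matrix")
        return M

    def collision_map(self, s, check_guard=True, ground=0.0, guard_tol=1e-8):
        s = _asstate(s)
        if check_guard:
            self._check_guard(s, ground, guard_tol)
        p = self.params
        return np.array(_g.cf_col(s[0], s[1], s[2], s[3], p.beta, p.r))

    def collision_jacobian(self, s):
        s = _asstate(s)
        p = self.params
        return np.array(
            _g.cf_coljac(s[0], s[1], s[2], s[3], p.beta, p.r)
        ).reshape(4, 4)

    def guard(self, s, ground=0.0):
        s = _asstate(s)
        return _g.cf_guard(s[0], s[1], self.params.r, ground)

    def guard_gradient(self, s):
        s = _asstate(s)
        return np.array(_g.cf_dguard(s[0], s[1], self.params.r))

    def guard_armed(self, s):
        s = _asstate(s)
        return (s[0] - s[1]) > MIN_INTERLEG_ANGLE

    def kinetic_energy(self, s):
        s = _asstate(s)
        p = self.params
        return _g.cf_ke(s[0], s[1], s[2], s[3], p.beta, p.r)

    def potential_energy(self, s):
        s = _asstate(s)
        p = self.params
        return _g.cf_pot(s[0], s[1], p.beta, p.gamma, p.r)

    def energy(self, s):
        return self.kinetic_energy(s) + self.potential_energy(s)

    def push_vector_field_term(self, s, force):
        s = _asstate(s)
        Q = force * np.array(_g.cf_qpush(s[0], s[1], self.params.r))
        acc = np.linalg.solve(self.mass_matrix(s), Q)
        return np.array([0.0, 0.0, acc[0], acc[1]])


_MODELS = {
    "point_el": PointFeetWalker,
    "point_ham": PointFeetHamiltonianWalker,
    "circular": CircularFeetWalker,
}


def make_model(name, params: WalkerParams) -> WalkerModel:
    """Instantiate a model by name: 'point_el', 'point_ham' or 'circular'."""
    try:
        return _MODELS[name](params)
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; choose from {sorted(_MODELS)}"
        ) from None


def _transform_jacobian(s_el, params):
    """Jacobian of the EL -> Hamiltonian state map at an EL state."""
    th, ph, thd, phd = _asstate(s_el)
    m11, m12, m22 = _g.pf_mass(ph, params.beta)
    Tq = np.array(_g.hm_tq(th, ph, thd, phd, params.beta)).reshape(2, 2)
    T = np.zeros((4, 4))
    T[0, 0] = T[1, 1] = 1.0
    T[2:, :2] = Tq
    T[2:, 2:] = [[m11, m12], [m12, m22]]
    return T


def lagrangian_to_hamiltonian(s_el, params: WalkerParams):
    """Map a POINT_EL state to POINT_HAM: p = M(q) qdot.

    The transform is nonlinear in the state because the mass matrix depends
    on the configuration; the round trip with
    :func:`hamiltonian_to_lagrangian` is the identity.
    """
    th, ph, thd, phd = _asstate(s_el)
    pt, pf = _g.hm_mom(th, ph, thd, phd, params.beta)
    return np.array([th, ph, pt, pf])


def hamiltonian_to_lagrangian(s_ham, params: WalkerParams):
    """Inverse of :func:`lagrangian_to_hamiltonian`: qdot = M(q)^-1 p."""
    th, ph, pt, pf = _asstate(s_ham)
    m11, m12, m22 = _g.pf_mass(ph, params.beta)
    det = m11 * m22 - m12 * m12
    if abs(det) < 1e-14:
        raise NonIntegrableStateError("singular mass matrix")
    thd = (m22 * pt - m12 * pf) / det
    phd = (-m12 * pt + m11 * pf) / det
    return np.array([th, ph, thd, phd])
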