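"""Symbolic derivation of the walker dynamics and code generation.

All model equations used by the package (vector fields, state Jacobians,
collision maps, event Jacobians, guards, energies) are derived here from
first principles -- Lagrangian mechanics for the swing phase and angular
momentum conservation for the instantaneous inelastic foot strike -- and
emitted as plain closed-form Python functions into ``_generated.py``.

The derivation doubles as an independent oracle in the test suite: the
generated closed forms are re-derived and cross-checked at test time, and
the point-feet equations are additionally verified against the published
simplest-walker limit (hip-mass-dominated walker, beta -> 0).

Conventions
-----------
Nondimensional units: leg length l = 1, gravity g = 1, time in sqrt(l/g).

Point-feet walker (hip mass M = 1, foot masses m = beta at the leg tips):
state s = (theta, phi, thetadot, phidot); theta is the stance-leg angle
measured counter-clockwise from the normal of the inclined plane, phi the
inter-leg angle (swing-leg absolute angle alpha = theta - phi).  The walker
progresses in +x of the slope frame as theta decreases.  Gravity in slope
coordinates is (sin gamma, -cos gamma).

Circular(arc)-feet walker: state s = (phi1, phi2, phi1dot, phi2dot); phi1 is
the swing-leg and phi2 the stance-leg angle from the ground normal, gravity
tilted by the slope angle gamma.  Arc feet of radius r have their centre on
the leg axis at distance 1 - r from the hip; the stance foot rolls without
slipping.  Point masses: hip 1, each leg tip beta.  At r = 0 the model
reduces exactly to the point-feet walker (phi2 = theta, phi1 = theta - phi).
"""

from __future__ import annotations

import os

import sympy as sp

__all__ = [
    "point_feet_exprs",
    "hamiltonian_exprs",
    "circular_feet_exprs",
    "generate",
]

_HEADER = '''"""Closed-form walker dynamics (auto-generated by compassgait.symbolic).

Do not edit by hand: regenerate with ``python -m compassgait.symbolic``.
All functions take and return plain floats / flat tuples so that they can be
compiled by numba.  Matrix-valued results are returned row-major.
"""

import math

'''


def _cross2(r, v):
    return r[0] * v[1] - r[1] * v[0]


def point_feet_exprs():
    """Derive the point-feet walker in Euler-Lagrange form.

    Returns a dict of sympy expressions keyed by quantity, together with the
    symbols used (``syms``).
    """
    TH, PH, THD, PHD = sp.symbols("TH PH THD PHD")
    b, g = sp.symbols("BETA GAMMA")

    t = sp.Symbol("t")
    th_f, ph_f = sp.Function("th")(t), sp.Function("ph")(t)

    hip = sp.Matrix([-sp.sin(th_f), sp.cos(th_f)])
    alpha = th_f - ph_f
    swf = hip + sp.Matrix([sp.sin(alpha), -sp.cos(alpha)])
    vh, vs = hip.diff(t), swf.diff(t)
    gvec = sp.Matrix([sp.sin(g), -sp.cos(g)])

    KE = sp.Rational(1, 2) * vh.dot(vh) + sp.Rational(1, 2) * b * vs.dot(vs)
    PE = -hip.dot(gvec) - b * swf.dot(gvec)
    L = KE - PE

    qdd = sp.Matrix([th_f.diff(t, 2), ph_f.diff(t, 2)])
    EL = sp.Matrix(
        [sp.diff(L.diff(q.diff(t)), t) - L.diff(q) for q in (th_f, ph_f)]
    )
    sol = sp.solve(EL, list(qdd), dict=True)[0]

    sub = {th_f.diff(t): THD, ph_f.diff(t): PHD, th_f: TH, ph_f: PH}
    acc = sp.Matrix([sp.trigsimp(sp.simplify(sol[qdd[0]])),
                     sp.trigsimp(sp.simplify(sol[qdd[1]]))]).subs(sub)
    f = sp.Matrix([THD, PHD, acc[0], acc[1]])

    state = sp.Matrix([TH, PH, THD, PHD])
    J = f.jacobian(state)

    M = sp.simplify(sp.hessian(KE, sp.Matrix([th_f.diff(t), ph_f.diff(t)]))).subs(sub)
    V = sp.simplify(PE).subs(sub)
    KE_s = sp.simplify(KE).subs(sub)

    # --- inelastic foot strike ------------------------------------------
    # Angular momentum of the whole system about the new contact point and
    # of the trailing leg about the hip are conserved; impulse acts at the
    # new contact only.
    thd_m, phd_m = sp.symbols("thdm phdm")
    thd_p, phd_p = sp.symbols("thdp phdp")

    hipc = sp.Matrix([-sp.sin(TH), sp.cos(TH)])
    swfc = hipc + sp.Matrix([sp.sin(TH - PH), -sp.cos(TH - PH)])

    def dvel(expr, d1, d2):
        return expr.diff(TH) * d1 + expr.diff(PH) * d2

    vh_m = dvel(hipc, thd_m, phd_m)

    THp, PHp = sp.symbols("THp PHp")
    hip_p = sp.Matrix([-sp.sin(THp), sp.cos(THp)]) + swfc
    swf_p = hip_p + sp.Matrix([sp.sin(THp - PHp), -sp.cos(THp - PHp)])
    relab = {THp: TH - PH, PHp: -PH}
    vh_p = (hip_p.diff(THp) * thd_p + hip_p.diff(PHp) * phd_p).subs(relab)
    vs_p = (swf_p.diff(THp) * thd_p + swf_p.diff(PHp) * phd_p).subs(relab)

    L_pre = _cross2(hipc - swfc, vh_m)  # feet: zero arm or at rest
    L_post = _cross2(hipc - swfc, vh_p) + b * _cross2(-swfc, vs_p)
    Lleg_pre = sp.Integer(0)  # trailing foot at rest pre-strike
    Lleg_post = b * _cross2(-hipc, vs_p)

    solc = sp.solve([sp.Eq(L_pre, L_post), sp.Eq(Lleg_pre, Lleg_post)],
                    [thd_p, phd_p], dict=True)[0]
    col = sp.Matrix([
        TH - PH,
        -PH,
        sp.trigsimp(sp.simplify(solc[thd_p])).subs({thd_m: THD, phd_m: PHD}),
        sp.trigsimp(sp.simplify(solc[phd_p])).subs({thd_m: THD, phd_m: PHD}),
    ])
    Gcol = col.jacobian(state)

    # guard: swing-foot height above the (possibly shifted) ground
    H = sp.Symbol("H")
    guard = sp.cos(TH) - sp.cos(TH - PH) - H
    dguard = sp.Matrix([guard.diff(v) for v in state])

    # generalized force of a unit horizontal (+x, tilted frame) force applied
    # at each leg's midpoint
    mid_st = hipc / 2
    mid_sw = hipc + sp.Matrix([sp.sin(TH - PH), -sp.cos(TH - PH)]) / 2
    xhat = sp.Matrix([1, 0])
    Q = sp.Matrix([
        (mid_st.diff(TH) + mid_sw.diff(TH)).dot(xhat),
        (mid_st.diff(PH) + mid_sw.diff(PH)).dot(xhat),
    ])

    return {
        "syms": (TH, PH, THD, PHD, b, g, H),
        "f": f, "J": J, "M": M, "V": V, "KE": KE_s,
        "col": col, "Gcol": Gcol,
        "guard": guard, "dguard": dguard, "Q": Q,
    }


def hamiltonian_exprs(pf=None):
    """Point-feet walker in Hamiltonian canonical form.

    State s = (theta, phi, p_theta, p_phi) with p = M(q) qdot.  Derived from
    H(q, p) = 1/2 p^T M^-1 p + V(q).
    """
    if pf is None:
        pf = point_feet_exprs()
    TH, PH, THD, PHD, b, g, H = pf["syms"]
    PT, PF = sp.symbols("PT PF")

    M = pf["M"]
    V = pf["V"]
    p = sp.Matrix([PT, PF])
    Minv = M.inv()
    Ham = sp.Rational(1, 2) * (p.T * Minv * p)[0, 0] + V

    f = sp.Matrix([
        Ham.diff(PT), Ham.diff(PF), -Ham.diff(TH), -Ham.diff(PH)
    ])
    state = sp.Matrix([TH, PH, PT, PF])
    J = f.jacobian(state)

    # momentum transform p = M(q) v and the Jacobian of the (EL -> HAM) state
    # map; its velocity block is M and its configuration block d(Mv)/dq.
    v = sp.Matrix([THD, PHD])
    mom = M * v
    Tq = mom.jacobian(sp.Matrix([TH, PH]))

    return {
        "syms": (TH, PH, PT, PF, THD, PHD, b, g),
        "f": f, "J": J, "H": Ham, "mom": mom, "Tq": Tq,
    }


def circular_feet_exprs():
    """Derive the arc-feet walker (rolling stance foot, tilted gravity)."""
    P1, P2, P1D, P2D = sp.symbols("P1 P2 P1D P2D")
    b, g, r = sp.symbols("BETA GAMMA R")

    t = sp.Symbol("t")
    p1_f, p2_f = sp.Function("p1")(t), sp.Function("p2")(t)

    C = sp.Matrix([-r * p2_f, r])  # rolling: contact translates with -r*phi2
    hip = C + (1 - r) * sp.Matrix([-sp.sin(p2_f), sp.cos(p2_f)])
    tip1 = hip + sp.Matrix([sp.sin(p1_f), -sp.cos(p1_f)])
    tip2 = hip + sp.Matrix([sp.sin(p2_f), -sp.cos(p2_f)])
    vh, v1, v2 = hip.diff(t), tip1.diff(t), tip2.diff(t)
    gvec = sp.Matrix([sp.sin(g), -sp.cos(g)])

    KE = sp.Rational(1, 2) * (vh.dot(vh) + b * v1.dot(v1) + b * v2.dot(v2))
    PE = -(hip.dot(gvec) + b * tip1.dot(gvec) + b * tip2.dot(gvec))
    L = KE - PE

    qd = sp.Matrix([p1_f.diff(t), p2_f.diff(t)])
    qdd = sp.Matrix([p1_f.diff(t, 2), p2_f.diff(t, 2)])
    EL = sp.Matrix(
        [sp.diff(L.diff(q.diff(t)), t) - L.diff(q) for q in (p1_f, p2_f)]
    )
    # EL = Mmat*qdd - F  (F collects velocity and gravity terms)
    Mmat = sp.expand(sp.hessian(KE, qd))
    F = sp.expand(-EL.subs({qdd[0]: 0, qdd[1]: 0}))
    acc = Mmat.inv() * F  # 2x2 inverse: adjugate over determinant

    sub = {p1_f.diff(t): P1D, p2_f.diff(t): P2D, p1_f: P1, p2_f: P2}
    acc = sp.Matrix([sp.cancel(sp.expand_trig(a).rewrite(sp.cos)) for a in acc]).subs(sub)
    f = sp.Matrix([P1D, P2D, acc[0], acc[1]])
    state = sp.Matrix([P1, P2, P1D, P2D])
    J = f.jacobian(state)

    Mmat_s = Mmat.subs(sub)
    V = PE.subs(sub)
    KE_s = KE.subs(sub)

    # --- foot strike -----------------------------------------------------
    p1d_m, p2d_m = sp.symbols("p1dm p2dm")
    p1d_p, p2d_p = sp.symbols("p1dp p2dp")

    Cc = sp.Matrix([-r * P2, r])
    hipc = Cc + (1 - r) * sp.Matrix([-sp.sin(P2), sp.cos(P2)])
    tip1c = hipc + sp.Matrix([sp.sin(P1), -sp.cos(P1)])
    tip2c = hipc + sp.Matrix([sp.sin(P2), -sp.cos(P2)])
    Csw = hipc + (1 - r) * sp.Matrix([sp.sin(P1), -sp.cos(P1)])
    contact = sp.Matrix([Csw[0], 0])

    def dvel(expr, d1, d2):
        return expr.diff(P1) * d1 + expr.diff(P2) * d2

    vh_m = dvel(hipc, p1d_m, p2d_m)
    v1_m = dvel(tip1c, p1d_m, p2d_m)
    v2_m = dvel(tip2c, p1d_m, p2d_m)

    # post-impact: leg 1 becomes the rolling stance leg
    Q1, Q2 = sp.symbols("Q1 Q2")
    C1p = sp.Matrix([-r * Q1, r])
    hip_p = C1p + (1 - r) * sp.Matrix([-sp.sin(Q1), sp.cos(Q1)])
    tip1_p = hip_p + sp.Matrix([sp.sin(Q1), -sp.cos(Q1)])
    tip2_p = hip_p + sp.Matrix([sp.sin(Q2), -sp.cos(Q2)])
    subq = {Q1: P1, Q2: P2}
    vh_p = (hip_p.diff(Q1) * p1d_p + hip_p.diff(Q2) * p2d_p).subs(subq)
    v1_p = (tip1_p.diff(Q1) * p1d_p + tip1_p.diff(Q2) * p2d_p).subs(subq)
    v2_p = (tip2_p.diff(Q1) * p1d_p + tip2_p.diff(Q2) * p2d_p).subs(subq)

    L_pre = (_cross2(hipc - contact, vh_m) + b * _cross2(tip1c - contact, v1_m)
             + b * _cross2(tip2c - contact, v2_m))
    L_post = (_cross2(hipc - contact, vh_p) + b * _cross2(tip1c - contact, v1_p)
              + b * _cross2(tip2c - contact, v2_p))
    Lleg_pre = b * _cross2(tip2c - hipc, v2_m)
    Lleg_post = b * _cross2(tip2c - hipc, v2_p)

    A, rhs = sp.linear_eq_to_matrix(
        [sp.expand(L_post - L_pre), sp.expand(Lleg_post - Lleg_pre)],
        [p1d_p, p2d_p],
    )
    solv = A.LUsolve(rhs)
    solv = sp.Matrix([sp.cancel(s) for s in solv]).subs({p1d_m: P1D, p2d_m: P2D})

    # relabel: leg 1 (new stance) -> slot 2, leg 2 (new swing) -> slot 1
    col = sp.Matrix([P2, P1, solv[1], solv[0]])
    Gcol = col.jacobian(state)

    H = sp.Symbol("H")
    guard = (1 - r) * (sp.cos(P2) - sp.cos(P1)) - H
    dguard = sp.Matrix([guard.diff(v) for v in state])

    mid1 = hipc + sp.Matrix([sp.sin(P1), -sp.cos(P1)]) / 2
    mid2 = hipc + sp.Matrix([sp.sin(P2), -sp.cos(P2)]) / 2
    xhat = sp.Matrix([1, 0])
    Qf = sp.Matrix([
        (mid1.diff(P1) + mid2.diff(P1)).dot(xhat),
        (mid1.diff(P2) + mid2.diff(P2)).dot(xhat),
    ])

    return {
        "syms": (P1, P2, P1D, P2D, b, g, r, H),
        "f": f, "J": J, "M": Mmat_s, "V": V, "KE": KE_s,
        "col": col, "Gcol": Gcol,
        "guard": guard, "dguard": dguard, "Q": Qf,
    }


def _emit(name, args, exprs, doc=""):
    flat = []
    for e in exprs:
        if isinstance(e, sp.MatrixBase):
            flat.extend(list(e))
        else:
            flat.append(e)
    reps, outs = sp.cse(flat, optimizations="basic")
    lines = [f"def {name}({', '.join(args)}):"]
    if doc:
        lines.append(f'    """{doc}"""')
    for sym, e in reps:
        lines.append(f"    {sym} = {sp.pycode(e)}")
    def _code(o):
        # keep return tuples float-homogeneous (numba-friendly)
        if getattr(o, "is_number", False):
            return repr(float(o))
        return sp.pycode(o)

    body = ", ".join(_code(o) for o in outs)
    lines.append(f"    return ({body})")
    return "\n".join(lines) + "\n\n"


def generate(path=None):
    """Regenerate ``_generated.py`` next to this module."""
    if path is None:
        path = os.path.join(os.path.dirname(__file__), "_generated.py")

    pf = point_feet_exprs()
    TH, PH, THD, PHD, b, g, H = pf["syms"]
    s4 = ["TH", "PH", "THD", "PHD"]
    chunks = [_HEADER]
    chunks.append(_emit("pf_f", s4 + ["BETA", "GAMMA"], [pf["f"]],
                        "Point-feet vector field (Euler-Lagrange form)."))
    chunks.append(_emit("pf_jac", s4 + ["BETA", "GAMMA"], [pf["J"]],
                        "Point-feet state Jacobian, row-major 4x4."))
    chunks.append(_emit("pf_mass", ["PH", "BETA"],
                        [pf["M"][0, 0], pf["M"][0, 1], pf["M"][1, 1]],
                        "Mass matrix entries (m11, m12, m22); depends on phi only."))
    chunks.append(_emit("pf_pot", ["TH", "PH", "BETA", "GAMMA"], [pf["V"]],
                        "Gravitational potential, slope-tilted frame."))
    chunks.append(_emit("pf_ke", s4 + ["BETA"], [pf["KE"]],
                        "Kinetic energy of the moving masses."))
    chunks.append(_emit("pf_col", s4 + ["BETA"], [pf["col"]],
                        "Inelastic foot-strike map (relabelled post state)."))
    chunks.append(_emit("pf_coljac", s4 + ["BETA"], [pf["Gcol"]],
                        "Jacobian of the foot-strike map, row-major 4x4."))
    chunks.append(_emit("pf_guard", ["TH", "PH", "H"], [pf["guard"]],
                        "Swing-foot height above (possibly shifted) ground."))
    chunks.append(_emit("pf_dguard", ["TH", "PH"], [pf["dguard"]],
                        "State gradient of the guard."))
    chunks.append(_emit("pf_qpush", ["TH", "PH"], [pf["Q"]],
                        "Generalized force of a unit +x force at each leg midpoint."))

    hm = hamiltonian_exprs(pf)
    h4 = ["TH", "PH", "PT", "PF"]
    chunks.append(_emit("hm_f", h4 + ["BETA", "GAMMA"], [hm["f"]],
                        "Point-feet vector field (Hamiltonian canonical form)."))
    chunks.append(_emit("hm_jac", h4 + ["BETA", "GAMMA"], [hm["J"]],
                        "Hamiltonian state Jacobian, row-major 4x4."))
    chunks.append(_emit("hm_energy", h4 + ["BETA", "GAMMA"], [hm["H"]],
                        "The Hamiltonian H(q, p)."))
    chunks.append(_emit("hm_mom", ["TH", "PH", "THD", "PHD", "BETA"], [hm["mom"]],
                        "Conjugate momenta p = M(q) qdot."))
    chunks.append(_emit("hm_tq", ["TH", "PH", "THD", "PHD", "BETA"], [hm["Tq"]],
                        "d(M(q) qdot)/dq, row-major 2x2."))

    cf = circular_feet_exprs()
    c4 = ["P1", "P2", "P1D", "P2D"]
    chunks.append(_emit("cf_f", c4 + ["BETA", "GAMMA", "R"], [cf["f"]],
                        "Arc-feet vector field (rolling stance foot)."))
    chunks.append(_emit("cf_jac", c4 + ["BETA", "GAMMA", "R"], [cf["J"]],
                        "Arc-feet state Jacobian, row-major 4x4."))
    chunks.append(_emit("cf_mass", c4[:2] + ["BETA", "R"],
                        [cf["M"][0, 0], cf["M"][0, 1], cf["M"][1, 1]],
                        "Mass matrix entries (m11, m12, m22)."))
    chunks.append(_emit("cf_pot", c4[:2] + ["BETA", "GAMMA", "R"], [cf["V"]],
                        "Gravitational potential, tilted-gravity frame."))
    chunks.append(_emit("cf_ke", c4 + ["BETA", "R"], [cf["KE"]],
                        "Kinetic energy."))
    chunks.append(_emit("cf_col", c4 + ["BETA", "R"], [cf["col"]],
                        "Inelastic foot-strike map (legs swapped in the result)."))
    chunks.append(_emit("cf_coljac", c4 + ["BETA", "R"], [cf["Gcol"]],
                        "Jacobian of the foot-strike map, row-major 4x4."))
    chunks.append(_emit("cf_guard", c4[:2] + ["R", "H"], [cf["guard"]],
                        "Swing-arc lowest point height above ground."))
    chunks.append(_emit("cf_dguard", c4[:2] + ["R"], [cf["dguard"]],
                        "State gradient of the guard."))
    chunks.append(_emit("cf_qpush", c4[:2] + ["R"], [cf["Q"]],
                        "Generalized force of a unit +x force at each leg midpoint."))

    with open(path, "w") as fh:
        fh.write("".join(chunks))
    return path


if __name__ == "__main__":
    out = generate()
    print(f"wrote {out}")
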