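"""Compiled Dormand-Prince 5(4) integrator with foot-strike event location.

This is the performance-critical core behind :mod:`compassgait.simulate`:
an adaptive RK45 with cubic-Hermite dense output, boolean-bisection event
location for the armed strike guard (and the hip-angle crossing used to
trigger push perturbations), and a variational-equation integrator for
fundamental (state-transition) matrices.  All entry points are numba-jitted;
the walker right-hand sides come from :mod:`compassgait._generated`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _generated as _g

# jit-compiled closed forms
_pf_f = njit(cache=True)(_g.pf_f)
_pf_jac = njit(cache=True)(_g.pf_jac)
_pf_mass = njit(cache=True)(_g.pf_mass)
_pf_qpush = njit(cache=True)(_g.pf_qpush)
_pf_guard = njit(cache=True)(_g.pf_guard)
_hm_f = njit(cache=True)(_g.hm_f)
_hm_jac = njit(cache=True)(_g.hm_jac)
_cf_f = njit(cache=True)(_g.cf_f)
_cf_jac = njit(cache=True)(_g.cf_jac)
_cf_mass = njit(cache=True)(_g.cf_mass)
_cf_qpush = njit(cache=True)(_g.cf_qpush)
_cf_guard = njit(cache=True)(_g.cf_guard)

_ARM_TH = -0.05
_ARM_INTERLEG = 0.08726646259971647  # 5 degrees

# integration outcome codes
OK_EVENT = 0
REACHED_TEND = 1
FALL_BOUNDS = 2
FALL_NUMERIC = 3

# event selectors
EV_STRIKE = 0
EV_HIP = 1
EV_NONE = 2
EV_BOTH = 3


@njit(cache=True)
def _rhs(mid, y, beta, gamma, r, push, out):
    if mid == 0:
        d0, d1, d2, d3 = _pf_f(y[0], y[1], y[2], y[3], beta, gamma)
        if push != 0.0:
            q0, q1 = _pf_qpush(y[0], y[1])
            m11, m12, m22 = _pf_mass(y[1], beta)
            det = m11 * m22 - m12 * m12
            d2 += push * (m22 * q0 - m12 * q1) / det
            d3 += push * (-m12 * q0 + m11 * q1) / det
    elif mid == 1:
        d0, d1, d2, d3 = _hm_f(y[0], y[1], y[2], y[3], beta, gamma)
        if push != 0.0:
            q0, q1 = _pf_qpush(y[0], y[1])
            d2 += push * q0
            d3 += push * q1
    else:
        d0, d1, d2, d3 = _cf_f(y[0], y[1], y[2], y[3], beta, gamma, r)
        if push != 0.0:
            q0, q1 = _cf_qpush(y[0], y[1], r)
            m11, m12, m22 = _cf_mass(y[0], y[1], beta, r)
            det = m11 * m22 - m12 * m12
            d2 += push * (m22 * q0 - m12 * q1) / det
            d3 += push * (-m12 * q0 + m11 * q1) / det
    out[0] = d0
    out[1] = d1
    out[2] = d2
    out[3] = d3


@njit(cache=True)
def _jac(mid, y, beta, gamma, r, out):
    if mid == 0:
        j = _pf_jac(y[0], y[1], y[2], y[3], beta, gamma)
    elif mid == 1:
        j = _hm_jac(y[0], y[1], y[2], y[3], beta, gamma)
    else:
        j = _cf_jac(y[0], y[1], y[2], y[3], beta, gamma, r)
    for i in range(16):
        out[i // 4, i % 4] = j[i]


@njit(cache=True)
def _guard_val(mid, y, r, ground):
    if mid <= 1:
        return _pf_guard(y[0], y[1], ground)
    return _cf_guard(y[0], y[1], r, ground)


@njit(cache=True)
def _armed(mid, y):
    if mid <= 1:
        return y[0] < _ARM_TH
    return (y[0] - y[1]) > _ARM_INTERLEG


@njit(cache=True)
def _hip_angle(mid, y):
    if mid <= 1:
        return y[1]
    return y[0] - y[1]


@njit(cache=True)
def _stance_angle(mid, y):
    if mid <= 1:
        return y[0]
    return y[1]


@njit(cache=True)
def _hermite(h, y0, f0, y1, f1, s, out):
    s2 = s * s
    s3 = s2 * s
    h00 = 2.0 * s3 - 3.0 * s2 + 1.0
    h10 = s3 - 2.0 * s2 + s
    h01 = -2.0 * s3 + 3.0 * s2
    h11 = s3 - s2
    for i in range(4):
        out[i] = h00 * y0[i] + h10 * h * f0[i] + h01 * y1[i] + h11 * h * f1[i]


# Dormand-Prince coefficients
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (19372.0 / 6561.0, -25360.0 / 2187.0,
                          64448.0 / 6561.0, -212.0 / 729.0)
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0,
                                46732.0 / 5247.0, 49.0 / 176.0,
                                -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = (35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0,
                           -2187.0 / 6784.0, 11.0 / 84.0)
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0,
                                71.0 / 1920.0, -17253.0 / 339200.0,
                                22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True)
def integrate_segment(mid, beta, gamma, r, push, ground,
                      t0, y0, t_end, rtol, atol, event_kind,
                      rec_t, rec_y, rec_f, n0):
    """Integrate one smooth segment, recording accepted nodes.

    Returns (status, event_which, t_fin, y_fin, n_nodes) where ``status`` is
    one of OK_EVENT / REACHED_TEND / FALL_BOUNDS / FALL_NUMERIC and
    ``event_which`` distinguishes EV_STRIKE from EV_HIP when both are
    watched.  Nodes (t, y, f) are appended to rec_* starting at index n0.
    """
    cap = rec_t.shape[0]
    y = y0.copy()
    f = np.empty(4)
    _rhs(mid, y, beta, gamma, r, push, f)
    t = t0
    n = n0
    rec_t[n] = t
    for i in range(4):
        rec_y[n, i] = y[i]
        rec_f[n, i] = f[i]
    n += 1

    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    k7 = np.empty(4)
    ytmp = np.empty(4)
    ynew = np.empty(4)
    ymid = np.empty(4)

    h = min(1e-3, t_end - t0)
    hmax = 0.2
    hmin = 1e-13

    g_prev = _guard_val(mid, y, r, ground)
    armed_prev = _armed(mid, y)
    hip_prev = _hip_angle(mid, y)
    cond_prev = armed_prev and (g_prev <= 0.0)

    while t < t_end:
        if h > t_end - t:
            h = t_end - t
        if h < hmin:
            return FALL_NUMERIC, -1, t, y, n

        # one DP45 step (FSAL structure, k1 = f)
        for i in range(4):
            ytmp[i] = y[i] + h * _A21 * f[i]
        _rhs(mid, ytmp, beta, gamma, r, push, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A31 * f[i] + _A32 * k2[i])
        _rhs(mid, ytmp, beta, gamma, r, push, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A41 * f[i] + _A42 * k2[i] + _A43 * k3[i])
        _rhs(mid, ytmp, beta, gamma, r, push, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A51 * f[i] + _A52 * k2[i] + _A53 * k3[i]
                                  + _A54 * k4[i])
        _rhs(mid, ytmp, beta, gamma, r, push, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (_A61 * f[i] + _A62 * k2[i] + _A63 * k3[i]
                                  + _A64 * k4[i] + _A65 * k5[i])
        _rhs(mid, ytmp, beta, gamma, r, push, k6)
        for i in range(4):
            ynew[i] = y[i] + h * (_B1 * f[i] + _B3 * k3[i] + _B4 * k4[i]
                                  + _B5 * k5[i] + _B6 * k6[i])
        _rhs(mid, ynew, beta, gamma, r, push, k7)

        # scaled error norm
        errnorm = 0.0
        ok = True
        for i in range(4):
            if not np.isfinite(ynew[i]):
                ok = False
                break
            e = h * (_E1 * f[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                     + _E6 * k6[i] + _E7 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            errnorm += (e / sc) ** 2
        if not ok:
            h *= 0.25
            if h < hmin:
                return FALL_NUMERIC, -1, t, y, n
            continue
        errnorm = np.sqrt(errnorm / 4.0)

        if errnorm > 1.0:
            fac = max(0.2, 0.8 * errnorm ** -0.2)
            h *= fac
            continue

        # accepted
        t_new = t + h

        # --- event detection on (t, t_new) ------------------------------
        if event_kind != EV_NONE:
            hit = -1
            g_new = _guard_val(mid, ynew, r, ground)
            armed_new = _armed(mid, ynew)
            cond_new = armed_new and (g_new <= 0.0)
            hip_new = _hip_angle(mid, ynew)
            if event_kind != EV_HIP and cond_new and not cond_prev:
                hit = EV_STRIKE
            elif event_kind != EV_STRIKE and (
                    (hip_prev < 0.0 <= hip_new) or (hip_prev > 0.0 >= hip_new)):
                hit = EV_HIP
            if hit >= 0:
                lo = 0.0
                hi = 1.0
                if hit == EV_STRIKE:
                    for _ in range(80):
                        md = 0.5 * (lo + hi)
                        _hermite(h, y, f, ynew, k7, md, ymid)
                        if _armed(mid, ymid) and (
                                _guard_val(mid, ymid, r, ground) <= 0.0):
                            hi = md
                        else:
                            lo = md
                else:
                    sign0 = hip_prev
                    for _ in range(80):
                        md = 0.5 * (lo + hi)
                        _hermite(h, y, f, ynew, k7, md, ymid)
                        hm = _hip_angle(mid, ymid)
                        if (sign0 < 0.0 and hm >= 0.0) or (
                                sign0 > 0.0 and hm <= 0.0):
                            hi = md
                        else:
                            lo = md
                t_ev = t + hi * h
                _hermite(h, y, f, ynew, k7, hi, ymid)
                _rhs(mid, ymid, beta, gamma, r, push, k2)
                if n >= cap:
                    return FALL_NUMERIC, -1, t_ev, ymid, n
                rec_t[n] = t_ev
                for i in range(4):
                    rec_y[n, i] = ymid[i]
                    rec_f[n, i] = k2[i]
                n += 1
                return OK_EVENT, hit, t_ev, ymid.copy(), n
            g_prev = g_new
            armed_prev = armed_new
            hip_prev = hip_new
            cond_prev = cond_new

        t = t_new
        for i in range(4):
            y[i] = ynew[i]
            f[i] = k7[i]
        if n >= cap:
            return FALL_NUMERIC, -1, t, y, n
        rec_t[n] = t
        for i in range(4):
            rec_y[n, i] = y[i]
            rec_f[n, i] = f[i]
        n += 1

        if abs(_stance_angle(mid, y)) > 1.5707963267948966:
            return FALL_BOUNDS, -1, t, y, n

        fac = 5.0 if errnorm == 0.0 else min(5.0, 0.8 * errnorm ** -0.2)
        h = min(h * fac, hmax)

    return REACHED_TEND, -1, t, y, n


@njit(cache=True)
def integrate_variational(mid, beta, gamma, r, y0, t_end, rtol, atol):
    """Integrate state + 4x4 fundamental matrix over [0, t_end].

    Returns (status, y(t_end), Phi(t_end)) with Phi(0) = I.  No event
    handling: the final time (e.g. a located strike time) is prescribed.
    """
    y = np.empty(20)
    for i in range(4):
        y[i] = y0[i]
    for i in range(16):
        y[4 + i] = 1.0 if i % 5 == 0 else 0.0

    f = np.empty(20)
    k2 = np.empty(20)
    k3 = np.empty(20)
    k4 = np.empty(20)
    k5 = np.empty(20)
    k6 = np.empty(20)
    k7 = np.empty(20)
    ytmp = np.empty(20)
    ynew = np.empty(20)
    jm = np.empty((4, 4))
    df = np.empty(4)

    h = min(1e-3, t_end)
    hmin = 1e-13
    t = 0.0

    # initial RHS
    _rhs(mid, y[:4], beta, gamma, r, 0.0, df)
    _jac(mid, y[:4], beta, gamma, r, jm)
    for i in range(4):
        f[i] = df[i]
    for i in range(4):
        for j in range(4):
            acc = 0.0
            for l in range(4):
                acc += jm[i, l] * y[4 + 4 * l + j]
            f[4 + 4 * i + j] = acc

    while t < t_end:
        if h > t_end - t:
            h = t_end - t
        if h < hmin:
            break

        for stage in range(6):
            if stage == 0:
                for i in range(20):
                    ytmp[i] = y[i] + h * _A21 * f[i]
                kk = k2
            elif stage == 1:
                for i in range(20):
                    ytmp[i] = y[i] + h * (_A31 * f[i] + _A32 * k2[i])
                kk = k3
            elif stage == 2:
                for i in range(20):
                    ytmp[i] = y[i] + h * (_A41 * f[i] + _A42 * k2[i]
                                          + _A43 * k3[i])
                kk = k4
            elif stage == 3:
                for i in range(20):
                    ytmp[i] = y[i] + h * (_A51 * f[i] + _A52 * k2[i]
                                          + _A53 * k3[i] + _A54 * k4[i])
                kk = k5
            elif stage == 4:
                for i in range(20):
                    ytmp[i] = y[i] + h * (_A61 * f[i] + _A62 * k2[i]
                                          + _A63 * k3[i] + _A64 * k4[i]
                                          + _A65 * k5[i])
                kk = k6
            else:
                for i in range(20):
                    ytmp[i] = y[i] + h * (_B1 * f[i] + _B3 * k3[i]
                                          + _B4 * k4[i] + _B5 * k5[i]
                                          + _B6 * k6[i])
                kk = k7
            _rhs(mid, ytmp[:4], beta, gamma, r, 0.0, df)
            _jac(mid, ytmp[:4], beta, gamma, r, jm)
            for i in range(4):
                kk[i] = df[i]
            for i in range(4):
                for j in range(4):
                    acc = 0.0
                    for l in range(4):
                        acc += jm[i, l] * ytmp[4 + 4 * l + j]
                    kk[4 + 4 * i + j] = acc

        for i in range(20):
            ynew[i] = ytmp[i]  # stage 6 ytmp is the 5th-order solution

        errnorm = 0.0
        bad = False
        for i in range(20):
            if not np.isfinite(ynew[i]):
                bad = True
                break
            e = h * (_E1 * f[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                     + _E6 * k6[i] + _E7 * k7[i])
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            errnorm += (e / sc) ** 2
        if bad:
            h *= 0.25
            continue
        errnorm = np.sqrt(errnorm / 20.0)
        if errnorm > 1.0:
            h *= max(0.2, 0.8 * errnorm ** -0.2)
            continue

        t += h
        for i in range(20):
            y[i] = ynew[i]
            f[i] = k7[i]
        fac = 5.0 if errnorm == 0.0 else min(5.0, 0.8 * errnorm ** -0.2)
        h = min(h * fac, 0.2)

    status = REACHED_TEND if abs(t - t_end) < 1e-10 else FALL_NUMERIC
    Phi = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            Phi[i, j] = y[4 + 4 * i + j]
    return status, y[:4].copy(), Phi


@njit(cache=True)
def jacobian_batch(mid, states, beta, gamma, r):
    """State Jacobians at many states, shape (n, 4, 4)."""
    n = states.shape[0]
    out = np.empty((n, 4, 4))
    jm = np.empty((4, 4))
    for k in range(n):
        _jac(mid, states[k], beta, gamma, r, jm)
        out[k] = jm
    return out


def hermite_sample(times, nodes_t, nodes_y, nodes_f):
    """Dense output: interpolate recorded nodes at ``times`` (vectorized).

    Cubic Hermite on each integration step, matching the interpolant used
    for event location.
    """
    times = np.asarray(times, dtype=float)
    idx = np.clip(np.searchsorted(nodes_t, times, side="right") - 1, 0,
                  len(nodes_t) - 2)
    t0 = nodes_t[idx]
    t1 = nodes_t[idx + 1]
    hstep = t1 - t0
    s = np.where(hstep > 0, (times - t0) / np.where(hstep == 0, 1, hstep), 0.0)
    s2, s3 = s * s, s ** 3
    h00 = 2 * s3 - 3 * s2 + 1
    h10 = s3 - 2 * s2 + s
    h01 = -2 * s3 + 3 * s2
    h11 = s3 - s2
    y0, y1 = nodes_y[idx], nodes_y[idx + 1]
    f0, f1 = nodes_f[idx], nodes_f[idx + 1]
    return (h00[:, None] * y0 + (h10 * hstep)[:, None] * f0
            + h01[:, None] * y1 + (h11 * hstep)[:, None] * f1)
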