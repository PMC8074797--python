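"""Closed-form walker dynamics (auto-generated by compassgait.symbolic).

Do not edit by hand: regenerate with ``python -m compassgait.symbolic``.
All functions take and return plain floats / flat tuples so that they can be
compiled by numba.  Matrix-valued results are returned row-major.
"""

import math

def pf_f(TH, PH, THD, PHD, BETA, GAMMA):
    """Point-feet vector field (Euler-Lagrange form)."""
    x0 = math.sin(PH)
    x1 = GAMMA - TH
    x2 = math.sin(x1)
    x3 = BETA*x0
    x4 = 2*PHD*THD
    x5 = PHD**2
    x6 = x3*x5
    x7 = THD**2
    x8 = x3*x7
    x9 = BETA*x2
    x10 = 2*PH
    x11 = BETA*math.sin(x10)
    x12 = BETA*math.sin(x1 + x10)
    x13 = 2*x7
    x14 = math.sin(-GAMMA + PH + TH)
    x15 = math.sin(PH + x1)
    return (THD, PHD, -((1/2)*x11*x7 - 1/2*x12 + x2 + x3*x4 - x6 - x8 + (1/2)*x9)/(BETA*x0**2 + 1), -(BETA*x14 + BETA*x15 + 4*PHD*THD*x3 - x0*x13 + x11*x13 - x11*x4 + x11*x5 - x12 + x14 + x15 + 2*x2 - 2*x6 - 4*x8 + x9)/(-BETA*math.cos(x10) + BETA + 2))

def pf_jac(TH, PH, THD, PHD, BETA, GAMMA):
    """Point-feet state Jacobian, row-major 4x4."""
    x0 = math.sin(PH)
    x1 = 1/(BETA*x0**2 + 1)
    x2 = GAMMA - TH
    x3 = math.cos(x2)
    x4 = BETA*x3
    x5 = 2*PH
    x6 = x2 + x5
    x7 = math.cos(x6)
    x8 = BETA*x7
    x9 = math.cos(PH)
    x10 = PHD**2
    x11 = THD**2
    x12 = PHD*THD
    x13 = x12*x9
    x14 = math.cos(x5)
    x15 = x11*x14
    x16 = math.sin(x5)
    x17 = BETA*x16
    x18 = x11*x17
    x19 = 2*x0
    x20 = x11*x19
    x21 = math.sin(x2)
    x22 = 4*BETA
    x23 = x0*x22
    x24 = -BETA*x10*x19 + BETA*x21 - BETA*math.sin(x6) + x12*x23 + 2*x21
    x25 = BETA*x1
    x26 = PHD*x19
    x27 = THD*x19
    x28 = THD*x16
    x29 = x26 - x27 + x28
    x30 = BETA*x14
    x31 = 1/(BETA - x30 + 2)
    x32 = -GAMMA + PH + TH
    x33 = math.cos(x32)
    x34 = BETA*x33
    x35 = PH + x2
    x36 = math.cos(x35)
    x37 = BETA*x36 + x36
    x38 = math.sin(x35)
    x39 = math.sin(x32)
    x40 = 2*BETA*x28
    x41 = PHD*x16
    x42 = 2*x31
    return (0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, x1*(x3 + (1/2)*x4 - 1/2*x8), x25*(x0*x1*x9*(-BETA*x20 + x18 + x24) + x10*x9 + x11*x9 - 2*x13 - x15 + x7), -x25*x29, x19*x25*(PHD - THD), x31*(2*x3 - x33 - x34 + x37 + x4 - x8), x31*(4*BETA*PHD*THD*x14 + 2*BETA*x10*x9 + 4*BETA*x11*x9 + 2*BETA*x16*x31*(BETA*x38 + BETA*x39 - PHD*x40 + x10*x17 - x11*x23 + 2*x18 - x20 + x24 + x38 + x39) + 2*BETA*x7 - 2*x10*x30 + 2*x11*x9 - x13*x22 - x15*x22 - x33 - x34 - x37), x42*(-BETA*x26 + BETA*x41 + THD*x23 + x27 - x40), BETA*x42*(x29 - x41))

def pf_mass(PH, BETA):
    """Mass matrix entries (m11, m12, m22); depends on phi only."""
    x0 = 2*BETA
    x1 = math.cos(PH)
    return (-x0*x1 + x0 + 1, BETA*(x1 - 1), BETA)

def pf_pot(TH, PH, BETA, GAMMA):
    """Gravitational potential, slope-tilted frame."""
    x0 = GAMMA - TH
    x1 = math.cos(x0)
    return (BETA*x1 - BETA*math.cos(PH + x0) + x1)

def pf_ke(TH, PH, THD, PHD, BETA):
    """Kinetic energy of the moving masses."""
    x0 = THD**2
    x1 = BETA*x0
    x2 = BETA*PHD*THD
    x3 = math.cos(PH)
    return ((1/2)*BETA*PHD**2 + (1/2)*x0 - x1*x3 + x1 + x2*x3 - x2)

def pf_col(TH, PH, THD, PHD, BETA):
    """Inelastic foot-strike map (relabelled post state)."""
    x0 = math.cos(PH)
    x1 = THD*x0/(BETA*math.sin(PH)**2 + 1)
    return (-PH + TH, -PH, x1, -x1*(x0 - 1))

def pf_coljac(TH, PH, THD, PHD, BETA):
    """Jacobian of the foot-strike map, row-major 4x4."""
    x0 = math.cos(PH)
    x1 = math.sin(PH)
    x2 = 1/(BETA*x1**2 + 1)
    x3 = 2*BETA*x0**2*x2
    x4 = THD*x1*x2
    x5 = x0*x2
    x6 = x0 - 1
    return (1.0, -1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, -x4*(x3 + 1), x5, 0.0, 0.0, x4*(2*x0 + x3*x6 - 1), -x5*x6, 0.0)

def pf_guard(TH, PH, H):
    """Swing-foot height above (possibly shifted) ground."""
    return (-H + math.cos(TH) - math.cos(PH - TH))

def pf_dguard(TH, PH):
    """State gradient of the guard."""
    x0 = math.sin(PH - TH)
    return (-x0 - math.sin(TH), x0, 0.0, 0.0)

def pf_qpush(TH, PH):
    """Generalized force of a unit +x force at each leg midpoint."""
    x0 = math.cos(PH - TH)
    return ((1/2)*x0 - 3/2*math.cos(TH), -1/2*x0)

def hm_f(TH, PH, PT, PF, BETA, GAMMA):
    """Point-feet vector field (Hamiltonian canonical form)."""
    x0 = math.cos(PH)
    x1 = x0 - 1
    x2 = PF*x1
    x3 = -BETA*x0**2 + BETA + 1
    x4 = 1/x3
    x5 = PT*x1
    x6 = 2*BETA
    x7 = x0*x6
    x8 = x6 - x7 + 1
    x9 = GAMMA - TH
    x10 = math.sin(x9)
    x11 = BETA*math.sin(PH + x9)
    x12 = math.sin(PH)
    x13 = -1/x3
    x14 = 2*PF
    return (x4*(PT - x2), x4*(-x5 + PF*x8/BETA), -BETA*x10 - x10 + x11, -1/2*PF*x12*x4*(PT - x0*x14*x4*x8 + x14 + x4*x5*x7) + (1/2)*PT*x12*x13*(PF + PT*x13*x7 - x13*x2*x7) - x11)

def hm_jac(TH, PH, PT, PF, BETA, GAMMA):
    """Hamiltonian state Jacobian, row-major 4x4."""
    x0 = math.cos(PH)
    x1 = x0**2
    x2 = BETA*x1
    x3 = BETA - x2 + 1
    x4 = 1/x3
    x5 = 2*BETA
    x6 = PT*x0
    x7 = x5*x6
    x8 = -x4*x7
    x9 = 2*PF
    x10 = x0*x9
    x11 = x0 - 1
    x12 = x11*x4
    x13 = BETA*x12
    x14 = math.sin(PH)
    x15 = x14*x4
    x16 = -x12
    x17 = x0*x5
    x18 = -x17 + x5 + 1
    x19 = x18*x4
    x20 = GAMMA - TH
    x21 = math.cos(x20)
    x22 = BETA*math.cos(PH + x20)
    x23 = -x22
    x24 = -x3
    x25 = 1/x24
    x26 = PF*x0
    x27 = x14**2
    x28 = PT*x25
    x29 = x27*x28*x5
    x30 = 2*x2*x28
    x31 = BETA*x27
    x32 = x25*x31
    x33 = 4*x32
    x34 = x25*x9
    x35 = x11*x34
    x36 = 8*x27/x24**2
    x37 = BETA**2*x1*x36
    x38 = PT*x37
    x39 = (1/2)*PT
    x40 = -x18
    x41 = x34*x40
    x42 = (1/2)*PF
    x43 = x12*x17 + 1
    return (0.0, x15*(PF + x10*x13 + x8), x4, x16, 0.0, x15*(PT - x10*x19 + x12*x7 + x9), x16, x19/BETA, BETA*x21 + x21 + x23, x22, 0.0, 0.0, x22, x23 + x25*x39*(-PF*x11*x37 - x2*x35 + x26*x33 + x26 - x29 + x30 + x31*x35 + x38) + x25*x42*(-PF*x2*x36*x40 - x1*x41 + x10 + x11*x29 - x11*x30 - x11*x38 + 8*x26*x32 + x27*x41 + x33*x6 + x6), x15*(-x13*x26 - x42*x43 - x42 - x8), x15*(PF*x0*x18*x4 - PF*(-x0*x19 + 1) - PF - x13*x6 - x39*x43 - x39))

def hm_energy(TH, PH, PT, PF, BETA, GAMMA):
    """The Hamiltonian H(q, p)."""
    x0 = GAMMA - TH
    x1 = math.cos(x0)
    x2 = math.cos(PH)
    x3 = x2 - 1
    x4 = (1/2)/(-BETA*x2**2 + BETA + 1)
    x5 = 2*BETA
    return (BETA*x1 - BETA*math.cos(PH + x0) + PF*x4*(-PT*x3 + PF*(-x2*x5 + x5 + 1)/BETA) - PT*x4*(PF*x3 - PT) + x1)

def hm_mom(TH, PH, THD, PHD, BETA):
    """Conjugate momenta p = M(q) qdot."""
    x0 = math.cos(PH)
    x1 = x0 - 1
    x2 = 2*BETA
    return (BETA*PHD*x1 + THD*(-x0*x2 + x2 + 1), BETA*(PHD + THD*x1))

def hm_tq(TH, PH, THD, PHD, BETA):
    """d(M(q) qdot)/dq, row-major 2x2."""
    x0 = BETA*math.sin(PH)
    return (0.0, x0*(-PHD + 2*THD), 0.0, -THD*x0)

def cf_f(P1, P2, P1D, P2D, BETA, GAMMA, R):
    """Arc-feet vector field (rolling stance foot)."""
    x0 = R**2
    x1 = math.sin(P1)
    x2 = x1**2
    x3 = x0*x2
    x4 = math.cos(P1)
    x5 = x4**2
    x6 = x0*x5
    x7 = math.sin(P2)
    x8 = x7**2
    x9 = x2*x8
    x10 = math.cos(P2)
    x11 = x10**2
    x12 = x11*x2
    x13 = x5*x8
    x14 = x11*x5
    x15 = BETA*x6
    x16 = 2*R
    x17 = x10*x16
    x18 = x17*x2
    x19 = x17*x5
    x20 = BETA*x3
    x21 = 2*x20
    x22 = BETA*x12
    x23 = BETA*x13
    x24 = BETA*x18
    x25 = x1*x7
    x26 = BETA*x25
    x27 = x26*x4
    x28 = 2*x10
    x29 = x3*x8
    x30 = x11*x3
    x31 = 4*x10
    x32 = 2*BETA
    x33 = x0*x25
    x34 = x33*x4
    x35 = BETA*R
    x36 = BETA*x28
    x37 = 1/(BETA*x29 + x11*x15 + x11*x6 - x12*x16 + x12 - x13*x16 + x13 - x14*x16 + x14 - x15*x28 + 2*x15*x8 + x15 - x16*x22 - x16*x23 - x16*x27 - x16*x9 + x18 + x19 - x20*x31 + x21 + x22 + x23 + x24 + x25*x31*x35*x4 - x27*x28 - x28*x3 - x28*x6 + x29 + x3 + x30*x32 + x30 + x32*x34 - x34*x36 + x6*x8 + x6 + x9)
    x38 = math.cos(GAMMA)
    x39 = x1*x38
    x40 = x0*x39
    x41 = x11*x39
    x42 = x17*x39
    x43 = x38*x7
    x44 = x4*x43
    x45 = R*x44
    x46 = P2D**2
    x47 = x4*x46
    x48 = x47*x7**3
    x49 = BETA*x41
    x50 = x0*x44
    x51 = x10*x44
    x52 = BETA*x45
    x53 = x1*x46
    x54 = x10**3*x53
    x55 = BETA*x48
    x56 = R**3
    x57 = x10*x53
    x58 = x56*x57
    x59 = x35*x39
    x60 = x47*x7
    x61 = x10*x60
    x62 = BETA*x54
    x63 = x53*x8
    x64 = R*x63
    x65 = x11*x53
    x66 = x16*x65
    x67 = 3*R
    x68 = x0*x57
    x69 = x11*x60
    x70 = math.sin(GAMMA)
    x71 = R*x70
    x72 = x25*x71
    x73 = x11*x40
    x74 = P1D**2
    x75 = BETA*x74
    x76 = x7*x75
    x77 = x2*x76
    x78 = R*x77
    x79 = x1*x75
    x80 = x4*x79
    x81 = x0*x80
    x82 = BETA*x0
    x83 = x54*x56
    x84 = x57*x8
    x85 = x10*x70
    x86 = x25*x85
    x87 = x5*x76
    x88 = x11*x80
    x89 = x28*x53
    x90 = BETA*x56
    x91 = BETA*x69
    x92 = x4*x70
    x93 = x35*x92
    x94 = x8*x92
    x95 = 2*x0
    x96 = 4*x0
    x97 = 3*x0
    x98 = x56*x63
    x99 = x56*x65
    x100 = x7*x74
    x101 = x100*x15
    x102 = x8*x80
    x103 = BETA*x84
    x104 = x28*x60
    x105 = BETA*x94
    x106 = x33*x70
    x107 = x100*x20
    x108 = BETA*x97
    x109 = x56*x69
    x110 = x0*x86
    x111 = BETA*x10
    x112 = BETA*x8
    x113 = x4*x59
    x114 = x2*x43
    x115 = x43*x5
    x116 = x1**3*x75
    x117 = R*x116
    x118 = R*x114
    x119 = BETA*x115
    x120 = x2*x71
    x121 = x5*x71
    x122 = x4**3*x76
    x123 = x46*x7
    x124 = R*x123
    x125 = x124*x2
    x126 = x5*x79
    x127 = R*x126
    x128 = x2*x85
    x129 = BETA*x121
    x130 = x1*x47
    x131 = x112*x130
    x132 = x111*x123
    x133 = x123*x15
    x134 = x11*x130
    x135 = BETA*x134
    x136 = x130*x82
    return (P1D, P2D, -x37*(-BETA*x31*x40 + BETA*x42 - BETA*x51 - BETA*x64 - BETA*x66 + BETA*x86 - 4*BETA*x99 + R*x61 - R*x87 - x0*x104 - x0*x94 - x10*x101 + x10*x107 - x10*x50 + 3*x10*x52 + x10*x77 - x10*x87 + x10*x93 + x101 + x102*x16 - x102 + x103*x67 - x103 + x104*x90 + x105*x16 - x105*x95 - x105 - x106*x32 - x106 - x107 - x108*x61 + x108*x63 - x109*x32 - x109 + x11*x81 - x11*x93 + x110*x32 + x110 - 3*x111*x72 - 4*x112*x68 - x16*x41 - x16*x49 - x16*x88 + x16*x94 + x17*x44 + x17*x80 - x18*x76 + x19*x76 - x28*x40 - x28*x72 - x28*x81 + x32*x40 + x32*x50 + x32*x72 + x32*x73 + x32*x83 - x32*x98 + x35*x61 - x36*x50 + x36*x98 + x40 + x41 + x42 - x45 - x48*x56 - x48*x67 + x48*x97 + x48 + x49 + x50 - x51 - x52 + x54*x67 - x54*x97 - x54 - 2*x55*x56 - x55*x67 + x55*x96 + x55 + x56*x61 + x58*x8 + x58 + x59*x8 + x60*x82 + x62*x67 - x62*x96 - x62 + x63*x95 - x64 + 6*x65*x82 + x65*x96 - x66 - x67*x69 + x67*x84 - x67*x91 - 3*x68*x8 - x68 + x69*x97 + x69 + x72 + x73 + x78 - x8*x81 + x81 - x82*x89 + x83 - x84 + x86 + x88 + x89*x90 + x91*x96 + x91 - x94 - x98 - 2*x99), -x37*(BETA*x118 - BETA*x123*x19 - BETA*x125 + BETA*x128 + R*x115 + R*x122 - x10*x113 + x10*x116 - x10*x117 - x10*x120 - x10*x121 - x10*x123*x20 + x10*x126 - x10*x127 - x10*x129 - x10*x130*x35 + x10*x133 + x10*x136 + x111*x39*x4 + x113 - x114 - x115 + x117 + x118 + x119*x16 - x119 + x120*x32 - x120*x36 + x120 + x121 - x122 + x123*x21 + x123*x24 + x123*x3 + x123*x6 - x124*x5 - x125 + x127 + x128 + x129 - x131*x16 + x131 - x132*x2 + x132*x5 + x133 - x134*x82 + x135*x16 - x135 + x136*x8 + x25*x93 - x26*x92 - x4*x77 + x4*x78 + x5*x85))

def cf_jac(P1, P2, P1D, P2D, BETA, GAMMA, R):
    """Arc-feet state Jacobian, row-major 4x4."""
    x0 = R**2
    x1 = math.sin(P1)
    x2 = x1**2
    x3 = x0*x2
    x4 = math.cos(P1)
    x5 = x4**2
    x6 = x0*x5
    x7 = math.sin(P2)
    x8 = x7**2
    x9 = x2*x8
    x10 = math.cos(P2)
    x11 = x10**2
    x12 = x11*x2
    x13 = x5*x8
    x14 = x11*x5
    x15 = BETA*x6
    x16 = 2*R
    x17 = x10*x2
    x18 = x16*x17
    x19 = R*x5
    x20 = 2*x10
    x21 = x19*x20
    x22 = BETA*x3
    x23 = BETA*x12
    x24 = BETA*x13
    x25 = x1*x4
    x26 = BETA*x25
    x27 = x26*x7
    x28 = x16*x9
    x29 = x14*x16
    x30 = x20*x3
    x31 = x3*x8
    x32 = x11*x3
    x33 = x6*x8
    x34 = 4*x10
    x35 = x0*x25
    x36 = 2*BETA
    x37 = x35*x36
    x38 = R*x10
    x39 = x26*x38
    x40 = 4*x7
    x41 = BETA*x31
    x42 = x11*x15
    x43 = x20*x35
    x44 = BETA*x7
    x45 = 1/(BETA*x18 + x11*x6 - x12*x16 + x12 - x13*x16 + x13 + x14 - x15*x20 + 2*x15*x8 + x15 - x16*x23 - x16*x24 - x16*x27 + x18 - x20*x27 - x20*x6 + x21 - x22*x34 + 2*x22 + x23 + x24 - x28 - x29 + x3 - x30 + x31 + x32*x36 + x32 + x33 + x37*x7 + x39*x40 + x41 + x42 - x43*x44 + x6 + x9)
    x46 = math.cos(GAMMA)
    x47 = x4*x46
    x48 = x0*x47
    x49 = P1D**2
    x50 = x15*x49
    x51 = x1*x46
    x52 = x51*x7
    x53 = R*x52
    x54 = math.sin(GAMMA)
    x55 = x4*x54
    x56 = x55*x7
    x57 = R*x56
    x58 = R**3
    x59 = P2D**2
    x60 = x4*x59
    x61 = x10*x60
    x62 = x58*x61
    x63 = x10*x52
    x64 = x10*x56
    x65 = x2*x7
    x66 = R*x65
    x67 = x11*x25
    x68 = x10*x65
    x69 = x3*x7
    x70 = x5*x7
    x71 = x10*x70
    x72 = x1*x8
    x73 = x4*x72
    x74 = x11*x35
    x75 = x10*x69
    x76 = x6*x7
    x77 = x0*x73
    x78 = x16*x67
    x79 = x20*x66
    x80 = R*x70
    x81 = x20*x80
    x82 = x16*x73
    x83 = x10*x16
    x84 = x25*x83
    x85 = x76 - x80
    x86 = -x10*x76 + x35 - x43 + x66 + x67 + x68 - x69 - x71 - x73 + x74 + x75 - x77 - x78 - x79 + x81 + x82 + x84 + x85
    x87 = x0*x51
    x88 = x11*x51
    x89 = x51*x83
    x90 = x47*x7
    x91 = R*x90
    x92 = x7**3
    x93 = x4*x92
    x94 = x59*x93
    x95 = BETA*x88
    x96 = x48*x7
    x97 = x10*x90
    x98 = BETA*x91
    x99 = x10**3
    x100 = x1*x99
    x101 = x100*x59
    x102 = BETA*x94
    x103 = x1*x59
    x104 = x10*x103
    x105 = x104*x58
    x106 = R*x72
    x107 = BETA*x106
    x108 = R*x61*x7
    x109 = BETA*x101
    x110 = x103*x8
    x111 = R*x110
    x112 = x103*x11
    x113 = x112*x16
    x114 = 3*R
    x115 = x0*x104
    x116 = x11*x7
    x117 = x116*x60
    x118 = x1*x54
    x119 = x118*x7
    x120 = R*x119
    x121 = x11*x87
    x122 = BETA*x49
    x123 = BETA*x0
    x124 = x60*x7
    x125 = BETA*x34
    x126 = 3*x10
    x127 = x101*x58
    x128 = x104*x8
    x129 = x10*x119
    x130 = x122*x80
    x131 = x103*x20
    x132 = BETA*x58
    x133 = BETA*x117
    x134 = BETA*x55
    x135 = x55*x8
    x136 = 2*x0
    x137 = 4*x0
    x138 = 3*x0
    x139 = x110*x58
    x140 = 2*x58
    x141 = x49*x7
    x142 = x141*x15
    x143 = BETA*x128
    x144 = BETA*x16
    x145 = x0*x20
    x146 = BETA*x20
    x147 = BETA*x135
    x148 = x0*x119
    x149 = BETA*x138
    x150 = 6*x123
    x151 = 4*x132
    x152 = BETA*x0*x61
    x153 = x115*x8
    x154 = BETA*x10
    x155 = 4*BETA
    x156 = BETA*x108 - BETA*x111 - BETA*x113 + BETA*x129 + BETA*x89 - BETA*x97 - R*x11*x134 + x0*x129 - x0*x135 - x10*x142 - x10*x96 + x101*x114 - x101*x138 - x101 - x102*x114 + x102*x137 - x102*x140 + x102 + x105*x8 + x105 + x107*x46 + x108 + x109*x114 - x109*x137 - x109 + x110*x136 + x110*x149 - x111 + x112*x137 - x112*x140 + x112*x150 - x112*x151 - x113 - x114*x117 + x114*x128 - x114*x133 + x114*x143 - x114*x94 - x115 + x117*x138 - x117*x58 + x117 + x119*x144 - 3*x120*x154 + x120 + x121*x36 + x121 + x122*x35 - x122*x43 + x122*x66 + x122*x67 + x122*x68 - x122*x69 - x122*x71 - x122*x73 + x122*x74 + x122*x75 - x122*x77 - x122*x78 - x122*x79 + x122*x81 + x122*x82 + x122*x84 + x123*x124 - x123*x131 + x124*x132*x20 - x124*x145 - x125*x87 + x126*x98 + x127*x36 + x127 - x128 - x129*x16 + x129 - x130 + x131*x132 + x133*x137 - x133*x140 + x133 + x134*x38 + x135*x16 - x135 - x136*x147 + x138*x94 + x139*x146 - x139*x36 - x139 + x142 - x143 + x146*x148 - x146*x96 + x147*x16 - x147 - x148*x36 - x148 - 3*x152*x7 - x153*x155 - 3*x153 - x16*x88 - x16*x95 + x16*x97 - x20*x87 + x36*x87 + x36*x96 - x58*x94 + x62*x7 + x87 + x88 + x89 - x91 + x94 + x95 + x96 - x97 - x98
    x157 = x47*x83
    x158 = x60*x8
    x159 = x136*x158
    x160 = x11*x60
    x161 = x11*x118
    x162 = BETA*x161
    x163 = x47*x8
    x164 = BETA*x163
    x165 = BETA*x53
    x166 = x7*x87
    x167 = x0*x56
    x168 = x103*x7
    x169 = x0*x168
    x170 = x149*x158
    x171 = x166*x20
    x172 = x167*x20
    x173 = x115*x44
    x174 = x141*x26
    x175 = x11*x47
    x176 = x54*x72
    x177 = x60*x99
    x178 = x103*x92
    x179 = BETA*x175
    x180 = BETA*x176
    x181 = x11*x48
    x182 = x24*x49
    x183 = x23*x49
    x184 = BETA*x177
    x185 = BETA*x178
    x186 = x103*x116
    x187 = x10*x158
    x188 = x158*x58
    x189 = BETA*x186
    x190 = BETA*x187
    x191 = R*x158
    x192 = BETA*x191
    x193 = x0*x176 + x10*x188 + x114*x177 + x114*x178 + x114*x184 + x114*x185 + x114*x186 + x114*x189 + x122*x14 - x122*x28 - x122*x29 - x122*x32 + x122*x9 + x125*x141*x35 + x126*x191 + x126*x192 + x136*x180 - x137*x184 - x137*x185 - x137*x189 - x137*x190 - x138*x177 - x138*x178 - x138*x186 - x138*x187 + x140*x184 + x140*x185 + x140*x189 - 8*x141*x39 + x146*x188 - x16*x175 - x16*x176 + x16*x182 + x16*x183 + x174*x34 + x175 + x176 + x177*x58 - x177 + x178*x58 - x178 + x179 + x180 + x181*x36 + x181 - x182 - x183 - x184 - x185 + x186*x58 - x186 - x187 - x189 - x190 + x41*x49 + x42*x49 - x50*x8
    x194 = x15*x7
    x195 = BETA*x71
    x196 = BETA*x73
    x197 = BETA*x66
    x198 = BETA*x67
    x199 = BETA*x68
    x200 = BETA*x75
    x201 = -BETA*x74 + BETA*x77 - BETA*x81 + x10*x194 + x154*x35 - x16*x196 + x16*x198 + x194 + x195 + x196 + x197*x20 - x197 - x198 - x199 - x200 + x36*x69 - x39 - x66 + x69 + x85
    x202 = 2*x45
    x203 = x201*x202
    x204 = x38*x47
    x205 = x168*x58
    x206 = x10*x118
    x207 = R*x160
    x208 = x160*x58
    x209 = x48*x8
    x210 = x16*x52
    x211 = x20*x52
    x212 = x20*x56
    x213 = R*x17
    x214 = x122*x213
    x215 = x104*x7
    x216 = BETA*x45
    x217 = 2*x216
    x218 = BETA*x100
    x219 = x1*x10
    x220 = x0*x219
    x221 = BETA*x93
    x222 = x1*x11
    x223 = x16*x222
    x224 = x219*x58
    x225 = x10*x72
    x226 = x4*x7
    x227 = x226*x38
    x228 = x58*x72
    x229 = x58*x93
    x230 = x116*x4
    x231 = BETA*x225
    x232 = BETA*x230
    x233 = x226*x58
    x234 = BETA*x72
    x235 = x4**3
    x236 = x235*x49
    x237 = R*x236
    x238 = x46*x5
    x239 = R*x238
    x240 = x1**3
    x241 = x10*x238
    x242 = x54*x65
    x243 = BETA*x47
    x244 = R*x243
    x245 = x46*x70
    x246 = R*x240
    x247 = x46*x80
    x248 = x10*x240
    x249 = R*x54
    x250 = x2*x249
    x251 = x249*x5
    x252 = x235*x7
    x253 = x59*x80
    x254 = x1*x19
    x255 = R*x252
    x256 = x10*x54
    x257 = x2*x256
    x258 = BETA*x251
    x259 = x59*x69
    x260 = x10*x246
    x261 = x219*x5
    x262 = x197*x59
    x263 = BETA*x60
    x264 = R*x219
    x265 = x4*x65
    x266 = BETA*x1
    x267 = x4*x66
    x268 = x19*x219
    x269 = x10*x59
    x270 = -BETA*x245 + BETA*x257 - x1*x123*x160 + x1*x244 - x10*x250 - x10*x251 - x10*x258 - 2*x107*x60 + x122*x246 + x122*x248 - x122*x252 + x122*x254 + x122*x255 - x122*x260 + x122*x261 - x122*x265 + x122*x267 - x122*x268 + x123*x60*x72 - x146*x250 - x146*x253 + x16*x160*x266 - x160*x266 + x194*x269 + x194*x59 + x195*x59 + x197*x46 - x199*x59 + x20*x262 - x200*x59 + x219*x243 - x219*x244 + x220*x263 + x234*x60 - x245 + x247*x36 + x247 + x249*x27 + x250*x36 + x250 + x251 - x253 + x256*x5 + x257 + x258 + x259*x36 + x259 - x262 - x263*x264 - x27*x54 - x46*x65 + x46*x66 - x59*x66 + x59*x76
    x271 = x4*x49
    x272 = x213*x59
    x273 = x10*x239
    x274 = x54*x66
    x275 = x269*x3
    x276 = x14*x59
    x277 = x59*x9
    x278 = 2*x25
    x279 = x54*x80
    x280 = R*x10*x2*x46
    x281 = -R*x10*x5*x59 - x10*x2*x46 + x269*x6 + x279 + x280 - x5*x54*x7
    x282 = x124*x155
    return (0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, x45*(3*BETA*R*x1*x10*x46*x7 + BETA*R*x1*x10*x54 + BETA*R*x1*x10*x59*x7 + 2*BETA*R*x1*x54*x8 + 2*BETA*R*x10*x2*x49 + 3*BETA*R*x10*x4*x54*x7 + 2*BETA*R*x11*x4*x46 + 2*BETA*R*x11*x4*x59 + BETA*R*x4*x59*x8 + 4*BETA*x0*x1*x4*x49*x7 + 2*BETA*x0*x1*x46*x7 + BETA*x0*x1*x59*x7 + 4*BETA*x0*x10*x4*x46 + 2*BETA*x0*x10*x4*x59 + 2*BETA*x0*x10*x49*x5 + BETA*x0*x2*x49 + 2*BETA*x0*x4*x54*x7 + 2*BETA*x1*x10*x58*x59*x7 + 4*BETA*x11*x4*x58*x59 + 2*BETA*x156*x45*x86 - BETA*x157 - BETA*x171 - BETA*x172 + 2*BETA*x4*x58*x59*x8 - BETA*x63 - BETA*x64 + 2*R*x1*x10*x46*x7 + R*x1*x10*x59*x7 + 2*R*x10*x4*x54*x7 + 2*R*x11*x4*x59 - R*x162 - R*x164 - 4*R*x174 + R*x4*x59*x8 + x0*x1*x46*x7 + 2*x0*x10*x4*x46 + x0*x10*x4*x59 + x0*x4*x54*x7 + x1*x10*x58*x59*x7 - x10*x166 - x10*x167 + 2*x11*x4*x58*x59 - x122*x21 - x122*x30 - x132*x20*x60 - x137*x160 - x144*x56 - x150*x160 - x157 - x159 - x165 - x169*x20 - x170 - 3*x173 - x193 - x36*x48 + x4*x58*x59*x8 - x48 - x50 - x53 - x57 - x62 - x63 - x64), x45*(-BETA*x20*x48 + BETA*x204 - BETA*x207 + BETA*x210 + BETA*x211 + BETA*x212 + BETA*x57 - x0*x161 + x0*x206 + x10*x122*x19 - 6*x10*x165 + x10*x22*x49 - x10*x48 - x10*x50 - x105*x155*x7 + x114*x162 + x114*x164 - x114*x179 - x114*x180 + x115*x40 + x118*x123*x20 - x118*x38 + x125*x166 + x125*x167 + x136*x160 - x136*x162 - x141*x37 - x144*x206 - x144*x215 + x149*x160 - x152 - 6*x154*x57 - x155*x166 + x156*x203 - x159 + x16*x161 + x16*x163 + x16*x174 - x16*x215 - x161 - x162 - x163 - x164 - 2*x166 - x169*x36 - x169 - x170 + x171 + x172 + 6*x173 + x188*x36 + x188 + x191 + x192 + x193 - x20*x205 + x204 + x205*x36 + x205 - x207 - x208*x36 - x208 - x209*x36 - x209 + x210 + x211 + x212 - x214 - x34*x53 - x34*x57), -P1D*x217*x86, P2D*x202*(BETA*x223 - BETA*x227 - x10*x228 - x10*x233 - x100*x114 + x100*x138 - x100*x58 + x100 - x106*x126 + x106 - x107*x126 + x107 - x114*x218 + x114*x221 + x114*x230 + x114*x232 + x114*x93 - x123*x226 - x136*x72 + x137*x218 - x137*x221 - x137*x222 + x137*x231 - x137*x232 + x138*x154*x226 + x138*x225 - x138*x230 - x138*x234 - x138*x93 - x140*x218 + x140*x222 + x140*x232 + x145*x226 - x146*x228 - x146*x233 - x150*x222 + x151*x222 + x218 + x220*x36 + x220 - x221 + x223 - x224*x36 - x224 + x225 - x227 + x228*x36 + x228 + x229*x36 + x229 + x230*x58 - x230 + x231 - x232 - x93), x216*(2*R*x1*x10*x4*x54 + 2*R*x1*x4*x46*x7 + 2*R*x1*x4*x59*x7 + R*x1*x49*x5*x7 + R*x10*x2*x4*x49 + R*x10*x235*x49 + 2*R*x11*x2*x59 - R*x2*x271 + R*x2*x46 + R*x240*x49*x7 + 2*R*x5*x59*x8 + 4*x0*x1*x10*x4*x59*x7 + x0*x11*x5*x59 + x0*x2*x59*x8 + 4*x1*x10*x4*x59*x7 - x1*x124*x136 - x1*x49*x70 - 2*x1*x90 - x10*x236 + x11*x5*x59 - x12*x59 - 8*x124*x264 - x13*x59 - x141*x240 - x16*x276 - x16*x277 - x17*x271 + x2*x59*x8 - x237 - x239 - x241 - x242 - x249*x278 - x256*x278 + 2*x270*x45*x86 - x272 + x273 + x274 + x275 - x281 - x32*x59 - x33*x59), x45*(8*BETA*R*x1*x10*x4*x59*x7 + BETA*R*x10*x2*x59 + 2*BETA*R*x11*x5*x59 + 2*BETA*R*x2*x59*x8 + BETA*x0*x1*x4*x59*x7 + BETA*x0*x11*x2*x59 + BETA*x0*x5*x59*x8 + BETA*x1*x10*x4*x54 + BETA*x1*x4*x46*x7 + BETA*x1*x49*x5*x7 + BETA*x10*x2*x4*x49 + BETA*x10*x235*x49 - BETA*x10*x237 + BETA*x10*x46*x5 + BETA*x11*x2*x59 - BETA*x141*x246 + BETA*x2*x54*x7 + BETA*x240*x49*x7 - BETA*x276 - BETA*x277 - BETA*x279 - BETA*x280 - BETA*x30*x59 + BETA*x5*x59*x8 - R*x124*x266 - x1*x130 - x1*x98 - x146*x239 - x15*x269 - x154*x249*x25 - x16*x23*x59 - x16*x24*x59 - 2*x197*x54 + 2*x201*x270*x45 - x214*x4 - x219*x282 - x220*x282 + x241 + x242 + x272 - x273 - x274 - x275 - x281 - x41*x59 - x42*x59), -P1D*x217*(x246 + x248 - x252 + x254 + x255 - x260 + x261 - x265 + x267 - x268), -P2D*x203)

def cf_mass(P1, P2, BETA, R):
    """Mass matrix entries (m11, m12, m22)."""
    x0 = math.sin(P1)
    x1 = math.cos(P1)
    x2 = math.sin(P2)
    x3 = math.cos(P2)
    x4 = R**2
    x5 = x2**2
    x6 = x3**2
    x7 = 2*R
    x8 = x3*x7
    x9 = 2*x4
    x10 = BETA*x5
    x11 = BETA*x6
    return (BETA*(x0**2 + x1**2), BETA*(R*x0*x2 + R*x1*x3 - R*x1 - x0*x2 - x1*x3), -4*BETA*x3*x4 + BETA*x8 + BETA*x9 - x10*x7 + x10*x9 + x10 - x11*x7 + x11*x9 + x11 - x3*x9 + x4*x5 + x4*x6 + x4 - x5*x7 + x5 - x6*x7 + x6 + x8)

def cf_pot(P1, P2, BETA, GAMMA, R):
    """Gravitational potential, tilted-gravity frame."""
    x0 = math.cos(GAMMA)
    x1 = math.cos(P2)
    x2 = R - 1
    x3 = math.sin(GAMMA)
    x4 = math.sin(P2)
    x5 = -x2
    x6 = P2*R + x4*x5
    x7 = R + x1*x5
    return (BETA*(x0*(-x1 + x7) - x3*(x4 - x6)) + BETA*(x0*(x7 - math.cos(P1)) - x3*(-x6 + math.sin(P1))) + x0*(R - x1*x2) + x3*x6)

def cf_ke(P1, P2, P1D, P2D, BETA, R):
    """Kinetic energy."""
    x0 = P2D**2
    x1 = math.sin(P2)
    x2 = x1**2
    x3 = R - 1
    x4 = math.cos(P2)
    x5 = x3*x4
    return ((1/2)*BETA*x0*(R**2*x2 + (R - x4 - x5)**2) + (1/2)*BETA*((P1D*math.sin(P1) + P2D*x1*x3)**2 + (-P1D*math.cos(P1) + P2D*R - P2D*x5)**2) + (1/2)*x0*x2*x3**2 + (1/2)*x0*(R - x5)**2)

def cf_col(P1, P2, P1D, P2D, BETA, R):
    """Inelastic foot-strike map (legs swapped in the result)."""
    x0 = math.cos(P2)
    x1 = x0**3
    x2 = R*x1
    x3 = math.cos(P1)
    x4 = x1*x3
    x5 = BETA*x2
    x6 = R**2
    x7 = math.sin(P2)
    x8 = x7**2
    x9 = x6*x8
    x10 = x0**2
    x11 = x10*x6
    x12 = R*x3
    x13 = x12*x8
    x14 = x0*x8
    x15 = R*x14
    x16 = x10*x12
    x17 = x1*x6
    x18 = math.sin(P1)
    x19 = x18**2
    x20 = x19*x8
    x21 = x10*x19
    x22 = BETA*x11
    x23 = 2*x3
    x24 = x14*x3
    x25 = 2*BETA
    x26 = BETA*x17
    x27 = BETA*x21
    x28 = x4*x6
    x29 = BETA*x16
    x30 = x3*x5
    x31 = BETA*x24
    x32 = 2*R
    x33 = x18*x7
    x34 = x0*x33
    x35 = x3*x9
    x36 = x0*x9
    x37 = x11*x3
    x38 = x3**2
    x39 = R*x38
    x40 = BETA*x8
    x41 = BETA*x10
    x42 = x33*x41
    x43 = x0*x13
    x44 = x0*x3
    x45 = BETA*x44
    x46 = x33*x45
    x47 = x19*x9
    x48 = x11*x19
    x49 = x22*x3
    x50 = x0*x35
    x51 = 3*BETA
    x52 = x25*x34
    x53 = x12*x52
    x54 = 2*x19
    x55 = 1/(BETA*x28 - BETA*x32*x34 + BETA*x47 + x11 + x13 + x15*x25 + x15 + x16 - x17 - x2*x23 + x2 - x20*x32 + x20 - x21*x32 + x21 - x22*x33 + x22*x54 + x22 + x24 - x25*x35 - x25*x36 + x25*x50 + x25*x9 - x26 - x27*x32 + x27 + x28 - x29 - x30 + x31 + x32*x42 - x35 - x36 - x37 + x39*x40 + x39*x41 + x4 - x42 - x43*x51 - 2*x43 - x46*x6 - x46 + x47 + x48 - x49 + x5 + x50 + x52*x6 + x53 + x9)
    x56 = P2D*x2
    x57 = R**3
    x58 = P2D*x8
    x59 = x57*x58
    x60 = P2D*x4
    x61 = P2D*x20
    x62 = P2D*x17
    x63 = BETA*P1D
    x64 = x0*x63
    x65 = x3**3*x64
    x66 = P2D*x5
    x67 = BETA*x60
    x68 = P2D*x21
    x69 = P2D*x28
    x70 = P2D*x47
    x71 = P2D*x36
    x72 = P2D*x18
    x73 = x7*x72
    x74 = x6*x73
    x75 = x38*x41
    x76 = P1D*x75
    x77 = P2D*x26
    x78 = P2D*x75
    x79 = P2D*R
    x80 = x0*x19
    x81 = x79*x80
    x82 = P2D*x57
    x83 = x80*x82
    x84 = x14*x82
    x85 = x57*x73
    x86 = 2*P2D
    x87 = x6*x80
    x88 = R*x63
    x89 = x18**3*x7
    x90 = x6*x64
    x91 = x19*x90
    x92 = x33*x63
    x93 = P2D*x29
    x94 = P2D*x9
    x95 = x41*x73
    x96 = P2D*x43
    x97 = x24*x82
    x98 = P1D*x38
    x99 = x3*x90
    x100 = BETA*P2D
    x101 = BETA*R
    x102 = x10*x73
    x103 = x102*x57
    x104 = x0*x74
    x105 = P2D*x30
    x106 = 3*R
    x107 = P2D*x22
    x108 = BETA*x23
    x109 = x0*x73
    x110 = P2D*x11
    x111 = x110*x33
    x112 = x0*x85
    x113 = BETA*x104
    x114 = R*x95
    x115 = 3*x100
    x116 = x101*x109
    x117 = 3*x74
    x118 = x22*x73
    x119 = BETA*x96 - P1D*x29 + x102 + x107 + x110
    x120 = P2D*x0**4
    x121 = BETA*x120
    x122 = x10*x58
    x123 = x7**3*x72
    x124 = BETA*x122
    x125 = x123*x6
    return (P2, P1, x55*(6*BETA*x112 - BETA*x12*x73 + BETA*x3*x74 + BETA*x38*x94 - BETA*x81 + P1D*x49 + P1D*x53 + P2D*x16 + P2D*x25*x87 + P2D*x35 - P2D*x37 + P2D*x45*x6 - 3*P2D*x49 - R*x65 + R*x68 - x0*x100*x39 - x101*x61 - x102*x106 - x103*x25 - x103 - 6*x104 - 3*x105 + x106*x109 - x107*x54 - x108*x112 - x108*x59 - 3*x109*x12 + 3*x111 + 3*x112 - 9*x113 - 4*x114 - x115*x50 + 3*x116 + x117*x44 + x117*x45 + 5*x118 + x119 + x12*x19*x64 - x12*x92 - x22*x98 - x23*x56 + x25*x59 + x25*x69 + x25*x70 + x25*x71 + x25*x74 - x25*x83 - x25*x84 - x25*x85 + x25*x97 + x27*x79 + 2*x27*x82 - x3*x33*x64 - x3*x59 + x3*x6*x92 - x3*x91 - x32*x61 + x32*x76 + x32*x78 - x33*x99 + x38*x90 + x38*x92 - x39*x92 + x44*x73 - x44*x85 - x45*x73 - x48*x86 - x50*x86 + x56 + x57*x68 + x59 - x6*x63*x89 + x60 + x61 - x62 + x65 + x66 + x67 + x69 + x70 + x71 + x74 - x76 - x77 - x78 - x81 - x83 - x84 - x85 + x86*x87 + x88*x89 + x91 + x93 + x95 + x96 + x97 - x99), x55*(BETA*x125 + P1D*R*x27 + P1D*x30 - P1D*x31 - P2D*x31 - x100*x13 - x101*x123 - x102*x32 + x105 + x110*x8 + x111 + x113 - x114 + x115*x15 - x116 + x118 + x119 - x120*x32 + x120*x6 + x120 - x121*x32 + x121*x6 + x121 - x122*x32 + x122 - x123*x32 + x123 - x124*x32 + x124 + x125 - x13*x63 + x13*x64 + x15*x86 + x20*x88 + x22*x58 + x25*x94 - x4*x63 + x40*x98 - x51*x71 + 2*x56 - 2*x62 + 2*x66 - x67 - 2*x71 + x76 - 2*x77 - x93 + x94))

def cf_coljac(P1, P2, P1D, P2D, BETA, R):
    """Jacobian of the foot-strike map, row-major 4x4."""
    x0 = R**2
    x1 = math.cos(P2)
    x2 = x1**2
    x3 = x0*x2
    x4 = BETA*x3
    x5 = math.sin(P1)
    x6 = x5**2
    x7 = x2*x6
    x8 = BETA*x7
    x9 = math.sin(P2)
    x10 = x9**2
    x11 = math.cos(P1)
    x12 = R*x11
    x13 = x10*x12
    x14 = x1*x10
    x15 = R*x14
    x16 = x3*x6
    x17 = x11*x14
    x18 = x0*x10
    x19 = x11*x18
    x20 = x1*x18
    x21 = R*x7
    x22 = x11**2
    x23 = x2*x22
    x24 = BETA*x23
    x25 = x10*x22
    x26 = BETA*R
    x27 = x1**3
    x28 = x11*x27
    x29 = x0*x28
    x30 = x18*x6
    x31 = BETA*x17
    x32 = x1*x19
    x33 = R*x27
    x34 = BETA*x33
    x35 = x11*x34
    x36 = x11*x4
    x37 = x2*x9
    x38 = x37*x5
    x39 = BETA*x38
    x40 = 2*R
    x41 = 2*BETA
    x42 = x19*x41
    x43 = x20*x41
    x44 = x1*x13
    x45 = 2*x6
    x46 = x4*x45
    x47 = x5*x9
    x48 = x4*x47
    x49 = BETA*x44
    x50 = x41*x9
    x51 = R*x5
    x52 = x1*x51
    x53 = x2*x51
    x54 = x0*x1
    x55 = x47*x54
    x56 = x11*x54
    x57 = BETA*x56
    x58 = x47*x57
    x59 = x12*x47
    x60 = x1*x59
    x61 = x12*x2
    x62 = x11*x3
    x63 = x61 - x62
    x64 = BETA*x61
    x65 = x18*x41 + x18 - x64
    x66 = x10*x6
    x67 = x0*x27
    x68 = BETA*x67
    x69 = x11*x33
    x70 = R*x66
    x71 = BETA*x11
    x72 = x1*x47
    x73 = x71*x72
    x74 = x28 + x29 + x30 + x33 + x34 + x66 - x67 - x68 - 2*x69 - 2*x70 - x73
    x75 = 1/(BETA*x29 + BETA*x30 + R*x24 + x13 + x15*x41 + x15 + x16 + x17 - x19 - x20 - 2*x21 + x25*x26 + x3 + x31 + x32*x41 + x32 - x35 - x36 - x39 + x4 - x40*x8 + x41*x55 + x41*x60 - x42 - x43 - 2*x44 + x46 - x48 - 3*x49 - x50*x52 + x50*x53 - x58 + x63 + x65 + x7 + x74 + x8)
    x76 = x27*x5
    x77 = P2D*x76
    x78 = x3*x5
    x79 = x18*x5
    x80 = x10*x51
    x81 = x5*x67
    x82 = x14*x5
    x83 = 2*x33
    x84 = 2*x11
    x85 = x2*x5
    x86 = x84*x85
    x87 = x10*x5
    x88 = x84*x87
    x89 = BETA*x53
    x90 = x34*x5
    x91 = x4*x5
    x92 = x1*x6
    x93 = BETA*x9
    x94 = x92*x93
    x95 = x5*x68
    x96 = x1*x22
    x97 = x93*x96
    x98 = x11*x37
    x99 = BETA*x98
    x100 = BETA*x82
    x101 = x20*x5
    x102 = 4*x5
    x103 = x11*x85
    x104 = x103*x41
    x105 = 2*x15
    x106 = 2*x5
    x107 = x54*x6
    x108 = x107*x93
    x109 = x22*x54
    x110 = x109*x93
    x111 = R*x92
    x112 = x111*x50
    x113 = x41*x5
    x114 = x113*x13
    x115 = BETA*x5
    x116 = 3*x115
    x117 = x1*x12
    x118 = x50*x56
    x119 = -x101*x41 - x117*x50 + x118 - x36*x9 + x41*x79
    x120 = -x100 - x101 - x102*x13 + x102*x36 - x102*x61 + x104 + x105*x5 + x106*x19 + x106*x62 + x108 - x110 - x112 - x114 + x116*x15 + x119 + x40*x97 + x42*x5 - 6*x5*x64 + x5*x83 + x50*x61 - x53 - x76 + x78 + x79 - x80 - x81 - x82 + x86 + x88 + x89 + x90 + x91 + x94 - x95 - x97 - x99
    x121 = P2D*x33
    x122 = R**3
    x123 = x10*x122
    x124 = P2D*x123
    x125 = P2D*x28
    x126 = P2D*x66
    x127 = P2D*x67
    x128 = x11**3
    x129 = x1*x128
    x130 = BETA*P1D
    x131 = P2D*x34
    x132 = BETA*x125
    x133 = P2D*x61
    x134 = P2D*x29
    x135 = P2D*x30
    x136 = P2D*x19
    x137 = P2D*x20
    x138 = x0*x47
    x139 = P2D*x138
    x140 = P2D*x122
    x141 = P1D*x24
    x142 = P2D*x68
    x143 = P2D*x24
    x144 = P2D*x111
    x145 = P2D*x62
    x146 = x140*x92
    x147 = x11*x124
    x148 = x1*x124
    x149 = x140*x47
    x150 = 2*x16
    x151 = 2*x107
    x152 = x5**3
    x153 = x152*x9
    x154 = R*x153
    x155 = P1D*x36
    x156 = x22*x47
    x157 = R*x8
    x158 = P2D*x64
    x159 = P2D*x18
    x160 = BETA*x22
    x161 = P2D*x57
    x162 = P2D*x44
    x163 = x1*x147
    x164 = P2D*x11
    x165 = R*x129
    x166 = P1D*x22
    x167 = x0*x153
    x168 = x130*x56
    x169 = x26*x96
    x170 = x140*x38
    x171 = 6*x55
    x172 = 3*P2D
    x173 = P2D*x53
    x174 = P2D*x4
    x175 = x149*x41
    x176 = 2*P2D
    x177 = x107*x41
    x178 = 2*x140
    x179 = P2D*x9
    x180 = 3*x179
    x181 = x179*x78
    x182 = x1*x149
    x183 = x12*x92
    x184 = x11*x138
    x185 = x166*x93
    x186 = x56*x6
    x187 = x11*x72
    x188 = BETA*x59
    x189 = BETA*P2D
    x190 = x189*x55
    x191 = x179*x89
    x192 = BETA*x172
    x193 = x52*x93
    x194 = x47*x56
    x195 = x174*x47
    x196 = 6*BETA
    x197 = x1*x11
    x198 = P1D*x41
    x199 = P2D*x3
    x200 = P1D*x64
    x201 = BETA*x162 + P2D*x38 + x174 + x199 - x200
    x202 = -BETA*x144 - P2D*x150 + P2D*x151 + P2D*x157 - P2D*x169 - P2D*x171 + P2D*x177 - P2D*x188 + P2D*x21 + P2D*x39 - P2D*x73 + x107*x130 + x109*x130 - x11*x182 - x121*x84 + x121 + x124*x41 + x124 + x125 - x126*x26 - x126*x40 + x126 - x127 + x129*x130 + x130*x154 + x130*x156 - x130*x165 - x130*x167 + x130*x183 + x130*x184 - x130*x186 - x130*x187 - x130*x59 + x131 + x132 + x133 + x134*x41 + x134 + x135*x41 + x135 + x136 + x137*x41 + x137 + x139*x41 + x139*x71 + x139 + x140*x7 + x141*x40 - x141 - x142 + x143*x40 - x143 - x144 - x145 - x146*x41 - x146 - x147*x41 - x147 - x148*x41 - x148 - x149 + x155 + x158 + x159*x160 + 3*x161*x47 + x161 + x162 + x163*x41 + x163 + x164*x72 - x166*x4 - x168*x47 - x168 - x170*x41 - x170 + x172*x193 + x172*x194 - x172*x35 - x172*x36 - x172*x60 - 3*x173*x9 - x174*x45 - x175*x197 - x175 - x176*x32 + x178*x8 + x180*x52 + 3*x181 + x182*x196 + 3*x182 - x185*x51 - 9*x190 - 4*x191 - x192*x32 + 5*x195 + x198*x60 + x201
    x203 = P2D*x79
    x204 = x11*x9
    x205 = x140*x204
    x206 = P1D*x128
    x207 = x206*x93
    x208 = P2D*x78
    x209 = P2D*x0
    x210 = x204*x209
    x211 = x124*x5
    x212 = x179*x96
    x213 = P2D*x98
    x214 = 2*x121
    x215 = x214*x5
    x216 = x22*x9
    x217 = P1D*x26
    x218 = P1D*x97
    x219 = x6*x93
    x220 = P2D*x5
    x221 = x15*x220
    x222 = x140*x9
    x223 = x222*x96
    x224 = x140*x98
    x225 = x148*x5
    x226 = P1D*x89
    x227 = x0*x185
    x228 = x130*x54
    x229 = x152*x228
    x230 = x209*x93
    x231 = x146*x9
    x232 = 4*x220
    x233 = 3*x9
    x234 = 3*x1
    x235 = 2*x1
    x236 = x1*x140
    x237 = x236*x5
    x238 = 3*x5
    x239 = x130*x96
    x240 = x11*x236*x93
    x241 = x239*x51
    x242 = P1D*x12*x219
    x243 = x179*x36
    x244 = x71*x85
    x245 = 4*x140
    x246 = P1D*x0*x219
    x247 = x179*x64
    x248 = P2D*x56*x93
    x249 = P2D*x89
    x250 = BETA*x77 - P1D*x104 + x249
    x251 = P2D*x99
    x252 = BETA*x221
    x253 = -x251 + x252
    x254 = x179*x6
    x255 = x246 - x254*x26
    x256 = P1D*x114
    x257 = x9**3
    x258 = x0*x257
    x259 = P2D*x258
    x260 = R*x257
    x261 = x11*x257
    x262 = BETA*x76
    x263 = BETA*x261
    x264 = R*x37
    x265 = x0*x261
    x266 = x260*x84
    x267 = BETA*x264
    x268 = x260*x71
    x269 = 2*x9
    x270 = 2*x0
    x271 = 4*x93
    x272 = x113*x61
    x273 = BETA*x102*x15 + x107*x50 - x111*x271 + x114 - x115*x19 + x119 + x233*x64 + x244 - x258*x41 - x258 + x260*x41 + x260 + x261 + x262 + x263*x270 + x263 + x264 + x265 - x266 - x267 - 3*x268 - x269*x61 - x272 - x3*x9 + x36*x5 + x4*x9 + x41*x53 - x41*x80 - x41*x82 - x41*x98 - x50*x54 + x50*x92 + x62*x9 - x71*x87 - 2*x90 - 2*x91 + x95 + x98
    x274 = x122*x77
    x275 = x259*x41
    x276 = 2*x179
    x277 = x172*x80
    x278 = x179*x41
    x279 = x278*x54
    x280 = P2D*x90
    x281 = x145*x9
    x282 = x130*x5
    x283 = 4*x9
    x284 = P2D*x268
    x285 = -P2D*x27*x5 + x284
    x286 = x187 + x63
    x287 = BETA*x75
    x288 = BETA*x28
    x289 = x122*x92
    x290 = x11*x123
    x291 = x1*x123
    x292 = x122*x47
    x293 = x1*x290
    x294 = x122*x38
    x295 = x292*x41
    x296 = x78*x9
    x297 = x1*x292
    x298 = BETA*x55
    x299 = 3*BETA
    x300 = x21 + x44
    x301 = x3 + x38 + x4 + x49
    x302 = x1**4
    x303 = P2D*x302
    x304 = BETA*x303
    x305 = x10*x2
    x306 = P2D*x305
    x307 = x257*x5
    x308 = 2*x127
    x309 = BETA*x306
    x310 = x259*x5
    x311 = x220*x260
    x312 = BETA*x13
    x313 = BETA*x310 - BETA*x311 + P1D*x157 - P1D*x288 - P1D*x31 + P1D*x35 - P2D*x193 + P2D*x307 - P2D*x31 - P2D*x312 + P2D*x35 + x0*x303 + x0*x304 + x10*x174 + x10*x199 - x13*x130 + x130*x25 + x130*x44 + x130*x70 + 2*x131 - x132 - x137*x299 - 2*x137 + x141 - 2*x142 + x15*x176 + x15*x192 - x158 + x159*x41 + x159 - x173*x269 + x181 + x190 - x191 + x195 + x201 + x214 - x303*x40 + x303 - x304*x40 + x304 - x306*x40 + x306 - x308 - x309*x40 + x309 + x310 - 2*x311
    x314 = x1*x257
    x315 = BETA*x302
    x316 = BETA*x305
    x317 = x258*x5
    x318 = x260*x5
    return (0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, -x75*(BETA*x220*x54 - P1D*x108 + P1D*x109*x113 + P1D*x110 + P1D*x112 + P1D*x91 - P1D*x94 + P2D*x81 - P2D*x88 - P2D*x94 + P2D*x97 + 3*R*x212 + x1*x152*x217 - x101*x176 - x101*x192 + x102*x145 + x102*x200 - x106*x133 - x106*x136 - x106*x155 + x107*x180 + x108*x172 - x109*x180 + 3*x11*x246 - x110*x172 + x113*x133 - x113*x136 - x117*x172*x93 - x117*x180 + x12*x220*x235 + x120*x202*x75 + x13*x220*x41 + x13*x232 + x133*x233 - x140*x86 - x144*x233 - x145*x233 - x164*x41*x85 - x172*x90 - x172*x91 + x173 + x176*x95 + x179*x22*x26 + 6*x179*x56 + x179*x92 + x198*x204*x6 + x203 - x205*x234 + x205*x41 + x205 + x206*x26*x9 - x207 - x208 + x209*x219 - x210*x41 - x210 - x211*x41 - x211 - x212 - x213 - x215 + x216*x217 - x217*x6*x9 - x218*x40 + x218 - x22*x230 + x221 + x223*x41 + x223 + x224*x41 + x224 + x225*x41 + x225 - x226 - x227 - x228*x5 - x229 - x231*x41 - x231 + x232*x36 - x232*x56 - x232*x57 + 4*x237*x71 + x237*x84 + x238*x239 - 6*x240 - 5*x241 - 5*x242 - 5*x243 - x244*x245 + 4*x247 + 9*x248 + x250 + x253 + x255 + x77), x75*(2*BETA*P1D*R*x1*x11*x9 + BETA*P1D*R*x1*x152 + 2*BETA*P1D*R*x11*x2*x5 + BETA*P1D*R*x128*x9 + BETA*P1D*x0*x1*x11*x5 + 2*BETA*P1D*x0*x1*x22*x9 + BETA*P1D*x0*x10*x11*x5 + BETA*P1D*x0*x11*x6*x9 + BETA*P1D*x0*x11*x9 + BETA*P1D*x1*x22*x5 + 2*BETA*P1D*x1*x22*x9 + BETA*P1D*x10*x11*x5 + 8*BETA*P2D*R*x1*x10*x5 + 11*BETA*P2D*R*x11*x2*x9 + 3*BETA*P2D*R*x2*x5 + BETA*P2D*R*x22*x9 + BETA*P2D*x0*x1*x11*x5 + 6*BETA*P2D*x0*x1*x11*x9 + 2*BETA*P2D*x0*x1*x22*x9 + 2*BETA*P2D*x0*x1*x5 + 8*BETA*P2D*x0*x1*x6*x9 + 9*BETA*P2D*x0*x10*x5 + 3*BETA*P2D*x0*x11*x2*x5 + 3*BETA*P2D*x0*x11*x257 + 7*BETA*P2D*x0*x2*x9 + 5*BETA*P2D*x0*x27*x5 + 4*BETA*P2D*x1*x10*x122*x5 + 4*BETA*P2D*x1*x122*x9 + 2*BETA*P2D*x1*x22*x9 + 2*BETA*P2D*x10*x11*x122*x5 + BETA*P2D*x10*x11*x5 + 4*BETA*P2D*x11*x122*x2*x9 + 6*BETA*P2D*x122*x2*x5 + 2*BETA*P2D*x122*x257 + 2*BETA*P2D*x122*x6*x9 + BETA*P2D*x27*x5 - BETA*x117*x220 - BETA*x245*x37 - BETA*x277 - P1D*x118 - P1D*x169*x283 + 6*P2D*R*x1*x10*x5 + 3*P2D*R*x10*x11*x5 + 8*P2D*R*x11*x2*x9 + 3*P2D*R*x2*x5 + P2D*R*x6*x9 + 4*P2D*x0*x1*x11*x9 + P2D*x0*x1*x5 + 6*P2D*x0*x1*x6*x9 + 6*P2D*x0*x10*x5 + 3*P2D*x0*x11*x2*x5 + 2*P2D*x0*x11*x257 + 5*P2D*x0*x2*x9 + 3*P2D*x0*x27*x5 + 2*P2D*x1*x10*x122*x5 + 2*P2D*x1*x122*x9 + 2*P2D*x1*x6*x9 + P2D*x10*x11*x122*x5 - 6*P2D*x101 + 2*P2D*x11*x122*x2*x9 + P2D*x11*x2*x5 + 3*P2D*x122*x2*x5 + P2D*x122*x257 + P2D*x122*x6*x9 - P2D*x244 - P2D*x41*x82 - 9*P2D*x91 - x0*x254*x41 - x1*x222*x84 - 10*x101*x189 - x103*x130 - x103*x140 - x104*x140 - x11*x230 - x116*x136 - x117*x276 - x117*x278 - x117*x282 - x121*x238 - x133*x238 - x136*x238 - x140*x261 - x144*x271 - 6*x144*x9 - x155*x5 - x164*x260 - x164*x87 - x172*x264 - x172*x267 - x176*x82 - x178*x263 - x178*x37 - x196*x211 + x202*x273*x75 - x207 - 6*x208 - 3*x211 - 4*x212*x26 - 3*x213 - x227 - x229 - 2*x231 - x237*x41 - x237 - 4*x240 - x241 - x242 - 12*x243 - x245*x94 - 3*x251 - x254*x270 - x255 - x256 - x259 - x274*x41 - x274 - x275 - x276*x54 - x277 - x279 - 4*x280 - 7*x281 - x285), -x287*(-x107 - x109 - x129 - x154 - x156 + x165 + x167 - x183 - x184 + x186 + x194 + x216*x51 + x22*x3 - x23*x40 + x23 - x235*x59 + x286 + x56 + x59), x75*(-BETA*x111 - BETA*x70 - x11*x297 - x111 + x122*x7 + 2*x122*x8 + x123*x41 + x123 + x138*x41 + x138*x71 + x138 - x150 + x151 + x157 + x160*x18 - x169 - x171 + x177 - x188 + x19 + 3*x193 + 3*x194 + x196*x297 - x197*x295 + x20 + x233*x52 - x233*x53 - x234*x59 + x24*x40 - x24 - x283*x89 + x286 + x288 - x289*x41 - x289 + x29*x41 - x290*x41 - x290 - x291*x41 - x291 - x292 + x293*x41 + x293 - x294*x41 - x294 - x295 + 3*x296 + 3*x297 - 9*x298 - x299*x32 + x30*x41 + x300 + x301 - 2*x32 - 3*x35 - 3*x36 + x39 + x43 - x46 + 5*x48 + x57 + 3*x58 + x64 + x74), x75*(P1D*x100 + P1D*x262 + P1D*x272 - P1D*x90 - P2D*x1*x12*x93 + P2D*x100 + P2D*x261 + P2D*x265 - P2D*x266 - x11*x198*x87 - x120*x313*x75 + x130*x80 - x133*x269 - x15*x282 + x189*x80 + x209*x263 + x213 + x226 + x243 - x247 + x248 + x250 - x252 + x256 - x280 + x281 - x284), x75*(BETA*P1D*x11*x2*x9 + BETA*P1D*x11*x257 + 4*BETA*P2D*R*x1*x257 + BETA*P2D*R*x10*x5 + 4*BETA*P2D*R*x27*x9 + BETA*P2D*x0*x1*x10*x5 + BETA*P2D*x0*x2*x5 + 3*BETA*P2D*x0*x257 + BETA*P2D*x0*x27*x5 + BETA*P2D*x11*x257 - BETA*x203 + 4*P2D*R*x1*x257 + 4*P2D*R*x27*x9 + P2D*x0*x1*x10*x5 + 2*P2D*x0*x2*x9 + 2*P2D*x0*x257 + P2D*x0*x27*x5 + P2D*x1*x10*x5 - P2D*x314*x41 - 2*x1*x259 - x1*x275 - x105*x220 - x11*x130*x260 - x142*x269 - x176*x260 - x176*x264 - x176*x314 - x192*x260 - x200*x9 - x215 - x247 - x249 - x253 - x27*x276 - x27*x278 + x273*x313*x75 + x279 - x280 - x285 - x308*x9), x287*(-x13 - x17 + x23 + x25 - x28 + x300 - x61 + x69 + x70), x75*(BETA*x317 - BETA*x318 + x0*x302 + x0*x315 + x10*x3 + x10*x4 + x105 + x15*x299 - x193 - x20*x299 - 2*x20 - x269*x53 - x288 + x296 + x298 + x301 - x302*x40 + x302 - x305*x40 + x305 + x307 - x31 - x312 - x315*x40 + x315 - x316*x40 + x316 + x317 - 2*x318 + 2*x34 + x35 + x48 + x65 - 2*x67 - 2*x68 + x83 - x89*x9))

def cf_guard(P1, P2, R, H):
    """Swing-arc lowest point height above ground."""
    return (-H + (R - 1)*(math.cos(P1) - math.cos(P2)))

def cf_dguard(P1, P2, R):
    """State gradient of the guard."""
    x0 = R - 1
    return (-x0*math.sin(P1), x0*math.sin(P2), 0.0, 0.0)

def cf_qpush(P1, P2, R):
    """Generalized force of a unit +x force at each leg midpoint."""
    x0 = math.cos(P2)
    return ((1/2)*math.cos(P1), -2*R + 2*x0*(R - 1) + (1/2)*x0)

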