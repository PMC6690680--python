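"""ten Tusscher–Panfilov 2006 (TP06) human ventricular myocyte model, epicardial variant.

This module holds the model constants, the gate kinetics and a readable
NumPy right-hand side.  All rate functions accept scalars or arrays so the
same code serves the reference ODE path (scipy) and the lookup-table
builder used by the fast fixed-step kernels in :mod:`epom._kernels`.

State vector layout (length 19)::

    0  V      membrane potential, mV
    1  Nai    intracellular Na+, mM
    2  Ki     intracellular K+, mM
    3  Cai    free cytosolic Ca2+, mM
    4  CaSR   sarcoplasmic-reticulum Ca2+, mM
    5  Cass   subspace Ca2+, mM
    6..16     gates m, h, j, xr1, xr2, xs, r, s, d, f, f2
    17 fCass  Ca-dependent ICaL inactivation gate
    18 Rbar   ryanodine-receptor adaptation variable

Calcium buffering uses the rapid-buffering (derivative) formulation, which
is the ODE-limit equivalent of the analytic-buffer stepping scheme of the
original source code.
"""

from __future__ import annotations

import numpy as np

# physical constants
R_GAS = 8314.472  # mJ/(mol K)
FARADAY = 96485.3415  # C/mol
TEMP = 310.0  # K
RTONF = R_GAS * TEMP / FARADAY  # mV

# external concentrations (control)
KO_CONTROL = 5.4  # mM
CAO = 2.0  # mM
NAO = 140.0  # mM

# cell geometry / capacitance
VC = 0.016404  # cytoplasmic volume, uL
VSR = 0.001094  # SR volume, uL
VSS = 0.00005468  # subspace volume, uL
CAPACITANCE = 0.185  # uF/cm^2 scaling used in concentration updates

# buffering
BUFC, KBUFC = 0.2, 0.001
BUFSR, KBUFSR = 10.0, 0.3
BUFSS, KBUFSS = 0.4, 0.00025

# SR fluxes / RyR
VMAXUP, KUP = 0.006375, 0.00025
VREL, VLEAK, VXFER = 0.102, 0.00036, 0.0038
K1P, K2P, K3, K4 = 0.15, 0.045, 0.060, 0.005
EC, MAXSR, MINSR = 1.5, 2.5, 1.0

# maximal conductances / peak currents (epicardial)
G_NA = 14.838  # nS/pF
G_CAL = 3.980e-5
G_KR = 0.153
G_KS = 0.392  # epi
G_K1 = 5.405
G_TO = 0.294  # epi
G_PK = 0.0146
G_PCA = 0.1238
G_BNA = 0.00029
G_BCA = 0.000592
P_NAK = 2.724
K_NACA = 1000.0

PKNA = 0.03
KM_K, KM_NA = 1.0, 40.0
KM_NAI, KM_CA, KSAT, GAMMA, ALPHA_NACA = 87.5, 1.38, 0.1, 0.35, 2.5
KP_CA = 0.0005

# ischemia overlay constant (ATP-sensitive K+ channel conductance)
G_KATP = 0.064  # mS/uF

#: names of the twelve scaled maximal conductances / peak currents, in the
#: order expected by every kernel in the package
PARAM_NAMES = (
    "g_na", "g_cal", "g_kr", "g_ks", "g_k1", "g_to",
    "g_pk", "g_pca", "g_bna", "g_bca", "p_nak", "k_naca",
)

N_STATE = 19
GATE_NAMES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2")
N_VGATES = len(GATE_NAMES)


def initial_state() -> np.ndarray:
    """Published TP06 resting initial conditions (epicardial)."""
    y = np.empty(N_STATE)
    y[0] = -86.2  # V
    y[1] = 7.67  # Nai
    y[2] = 138.3  # Ki
    y[3] = 0.00007  # Cai
    y[4] = 1.3  # CaSR
    y[5] = 0.00007  # Cass
    y[6] = 0.0  # m
    y[7] = 0.75  # h
    y[8] = 0.75  # j
    y[9] = 0.0  # xr1
    y[10] = 1.0  # xr2
    y[11] = 0.0  # xs
    y[12] = 0.0  # r
    y[13] = 1.0  # s
    y[14] = 0.0  # d
    y[15] = 1.0  # f
    y[16] = 1.0  # f2
    y[17] = 1.0  # fCass
    y[18] = 1.0  # Rbar
    return y


def baseline_scales() -> np.ndarray:
    return np.ones(len(PARAM_NAMES))


# ---------------------------------------------------------------------------
# voltage-dependent gate kinetics (epicardial)
# ---------------------------------------------------------------------------

def gate_inf_tau(v):
    """Steady states and time constants of the 11 voltage gates.

    Returns two arrays shaped ``(11,) + shape(v)`` ordered as GATE_NAMES.
    """
    v = np.asarray(v, dtype=float)
    exp = np.exp

    m_inf = 1.0 / (1.0 + exp((-56.86 - v) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + exp((-60.0 - v) / 5.0))
    b_m = 0.1 / (1.0 + exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + exp((v - 50.0) / 200.0))
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + exp((v + 71.55) / 7.43)) ** 2
    a_h = np.where(v >= -40.0, 0.0, 0.057 * exp(-(v + 80.0) / 6.8))
    b_h = np.where(
        v >= -40.0,
        0.77 / (0.13 * (1.0 + exp(-(v + 10.66) / 11.1))),
        2.7 * exp(0.079 * v) + 3.1e5 * exp(0.3485 * v),
    )
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    a_j = np.where(
        v >= -40.0,
        0.0,
        (-2.5428e4 * exp(0.2444 * v) - 6.948e-6 * exp(-0.04391 * v))
        * (v + 37.78)
        / (1.0 + exp(0.311 * (v + 79.23))),
    )
    b_j = np.where(
        v >= -40.0,
        0.6 * exp(0.057 * v) / (1.0 + exp(-0.1 * (v + 32.0))),
        0.02424 * exp(-0.01052 * v) / (1.0 + exp(-0.1378 * (v + 40.14))),
    )
    tau_j = 1.0 / (a_j + b_j)

    xr1_inf = 1.0 / (1.0 + exp((-26.0 - v) / 7.0))
    a_xr1 = 450.0 / (1.0 + exp((-45.0 - v) / 10.0))
    b_xr1 = 6.0 / (1.0 + exp((v + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1

    xr2_inf = 1.0 / (1.0 + exp((v + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + exp((-60.0 - v) / 20.0))
    b_xr2 = 1.12 / (1.0 + exp((v - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    xs_inf = 1.0 / (1.0 + exp((-5.0 - v) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + exp((5.0 - v) / 6.0))
    b_xs = 1.0 / (1.0 + exp((v - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    r_inf = 1.0 / (1.0 + exp((20.0 - v) / 6.0))
    tau_r = 9.5 * exp(-((v + 40.0) ** 2) / 1800.0) + 0.8

    s_inf = 1.0 / (1.0 + exp((v + 20.0) / 5.0))
    tau_s = 85.0 * exp(-((v + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + exp((v - 20.0) / 5.0)) + 3.0

    d_inf = 1.0 / (1.0 + exp((-8.0 - v) / 7.5))
    a_d = 1.4 / (1.0 + exp((-35.0 - v) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + exp((v + 5.0) / 5.0))
    c_d = 1.0 / (1.0 + exp((50.0 - v) / 20.0))
    tau_d = a_d * b_d + c_d

    f_inf = 1.0 / (1.0 + exp((v + 20.0) / 7.0))
    tau_f = (
        1102.5 * exp(-((v + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + exp((13.0 - v) / 10.0))
        + 180.0 / (1.0 + exp((v + 30.0) / 10.0))
        + 20.0
    )

    f2_inf = 0.67 / (1.0 + exp((v + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * exp(-((v + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + exp((25.0 - v) / 10.0))
        + 80.0 / (1.0 + exp((v + 30.0) / 10.0))
    )

    inf = np.stack([m_inf, h_inf, j_inf, xr1_inf, xr2_inf, xs_inf,
                    r_inf, s_inf, d_inf, f_inf, f2_inf])
    tau = np.stack([tau_m, tau_h, tau_j, tau_xr1, tau_xr2, tau_xs,
                    tau_r, tau_s, tau_d, tau_f, tau_f2])
    return inf, tau


# ---------------------------------------------------------------------------
# voltage-dependent current factors (used directly and for tables)
# ---------------------------------------------------------------------------

def rec_k1(v_minus_ek):
    """Inward-rectifier open probability as a function of V - EK."""
    x = np.asarray(v_minus_ek, dtype=float)
    a = 0.1 / (1.0 + np.exp(0.06 * (x - 200.0)))
    b = (3.0 * np.exp(0.0002 * (x + 100.0)) + np.exp(0.1 * (x - 10.0))) / (
        1.0 + np.exp(-0.5 * x)
    )
    return a / (a + b)


def ical_factors(v):
    """ICaL driving terms c1, c2 with ICaL = g*d*f*f2*fCass*(c1*Cass - c2).

    c1 = GCaL*2F*z*0.25*e^z/(e^z-1), c2 = GCaL*2F*z*Cao/(e^z-1) with
    z = 2(V-15)F/RT; the removable singularity at V = 15 mV is filled with
    its limit.
    """
    v = np.asarray(v, dtype=float)
    z = 2.0 * (v - 15.0) * FARADAY / (R_GAS * TEMP)
    small = np.abs(z) < 1e-8
    zs = np.where(small, 1.0, z)
    ez = np.exp(zs)
    frac = np.where(small, 1.0, zs / (ez - 1.0))
    c1 = G_CAL * 2.0 * FARADAY * 0.25 * np.where(small, 1.0, ez) * frac
    c2 = G_CAL * 2.0 * FARADAY * CAO * frac
    return c1, c2


def inak_vfactor(v):
    """Voltage dependence of the Na/K pump (without the Ko and Nai factors)."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * v / RTONF) + 0.0353 * np.exp(-v / RTONF)
    )


def inaca_factors(v):
    """NCX exponential factors e1 = exp(g*V*F/RT), e2 = exp((g-1)*V*F/RT)."""
    v = np.asarray(v, dtype=float)
    e1 = np.exp(GAMMA * v / RTONF)
    e2 = np.exp((GAMMA - 1.0) * v / RTONF)
    return e1, e2


def ipk_rec(v):
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + np.exp((25.0 - v) / 5.98))


# ---------------------------------------------------------------------------
# reference right-hand side
# ---------------------------------------------------------------------------

def currents(y, scales, ko=KO_CONTROL, f_katp=0.0, f_inhib=1.0):
    """All membrane currents (A/F) at state ``y``.

    Returns a dict keyed by current name.  ``scales`` follows PARAM_NAMES.
    The ischemia overlay enters here: I_Na and I_CaL are multiplied by
    ``f_inhib``, every K+-dependent term uses ``ko``, and I_K(ATP) follows
    the ATP-sensitive channel formulation
    f_KATP * G_KATP * (Ko/Ko_n)^0.24 * (V - EK).
    """
    (s_na, s_cal, s_kr, s_ks, s_k1, s_to,
     s_pk, s_pca, s_bna, s_bca, s_nak, s_naca) = scales
    v, nai, ki, cai, casr, cass = y[0], y[1], y[2], y[3], y[4], y[5]
    m, h, j, xr1, xr2, xs, r, s_gate, d, f, f2 = y[6:17]
    fcass = y[17]

    ek = RTONF * np.log(ko / ki)
    ena = RTONF * np.log(NAO / nai)
    eks = RTONF * np.log((ko + PKNA * NAO) / (ki + PKNA * nai))
    eca = 0.5 * RTONF * np.log(CAO / cai)
    sqrt_ko = np.sqrt(ko / KO_CONTROL)

    i_na = f_inhib * s_na * G_NA * m ** 3 * h * j * (v - ena)
    c1, c2 = ical_factors(v)
    i_cal = f_inhib * s_cal * d * f * f2 * fcass * (c1 * cass - c2)
    i_to = s_to * G_TO * r * s_gate * (v - ek)
    i_kr = s_kr * G_KR * sqrt_ko * xr1 * xr2 * (v - ek)
    i_ks = s_ks * G_KS * xs ** 2 * (v - eks)
    i_k1 = s_k1 * G_K1 * sqrt_ko * rec_k1(v - ek) * (v - ek)
    i_naca = s_naca * K_NACA * (
        inaca_factors(v)[0] * nai ** 3 * CAO
        - inaca_factors(v)[1] * NAO ** 3 * cai * ALPHA_NACA
    ) / (
        (KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
        * (1.0 + KSAT * inaca_factors(v)[1])
    )
    i_nak = s_nak * P_NAK * (ko / (ko + KM_K)) * (nai / (nai + KM_NA)) * inak_vfactor(v)
    i_pca = s_pca * G_PCA * cai / (KP_CA + cai)
    i_pk = s_pk * G_PK * ipk_rec(v) * (v - ek)
    i_bna = s_bna * G_BNA * (v - ena)
    i_bca = s_bca * G_BCA * (v - eca)
    i_katp = f_katp * G_KATP * (ko / KO_CONTROL) ** 0.24 * (v - ek)

    return {
        "i_na": i_na, "i_cal": i_cal, "i_to": i_to, "i_kr": i_kr,
        "i_ks": i_ks, "i_k1": i_k1, "i_naca": i_naca, "i_nak": i_nak,
        "i_pca": i_pca, "i_pk": i_pk, "i_bna": i_bna, "i_bca": i_bca,
        "i_katp": i_katp, "ek": ek,
    }


def rhs(t, y, scales, ko=KO_CONTROL, f_katp=0.0, f_inhib=1.0, i_stim=0.0):
    """Time derivative of the TP06 state (reference NumPy implementation)."""
    cur = currents(y, scales, ko, f_katp, f_inhib)
    v, nai, ki, cai, casr, cass = y[0], y[1], y[2], y[3], y[4], y[5]
    fcass, rbar = y[17], y[18]

    i_ion = (
        cur["i_na"] + cur["i_cal"] + cur["i_to"] + cur["i_kr"] + cur["i_ks"]
        + cur["i_k1"] + cur["i_naca"] + cur["i_nak"] + cur["i_pca"]
        + cur["i_pk"] + cur["i_bna"] + cur["i_bca"] + cur["i_katp"]
    )

    dy = np.empty_like(y)
    dy[0] = -(i_ion + i_stim)

    # gates
    inf, tau = gate_inf_tau(v)
    dy[6:17] = (inf - y[6:17]) / tau

    cass_sq = (cass / 0.05) ** 2
    fcass_inf = 0.6 / (1.0 + cass_sq) + 0.4
    tau_fcass = 80.0 / (1.0 + cass_sq) + 2.0
    dy[17] = (fcass_inf - fcass) / tau_fcass

    # RyR / SR calcium handling
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / casr) ** 2)
    k1 = K1P / kcasr
    k2 = K2P * kcasr
    dy[18] = -k2 * cass * rbar + K4 * (1.0 - rbar)
    o_rel = k1 * cass ** 2 * rbar / (K3 + k1 * cass ** 2)
    i_rel = VREL * o_rel * (casr - cass)
    i_leak = VLEAK * (casr - cai)
    i_up = VMAXUP / (1.0 + (KUP / cai) ** 2)
    i_xfer = VXFER * (cass - cai)

    buf_c = 1.0 / (1.0 + BUFC * KBUFC / (cai + KBUFC) ** 2)
    buf_sr = 1.0 / (1.0 + BUFSR * KBUFSR / (casr + KBUFSR) ** 2)
    buf_ss = 1.0 / (1.0 + BUFSS * KBUFSS / (cass + KBUFSS) ** 2)

    dy[3] = buf_c * (
        (i_leak - i_up) * VSR / VC
        + i_xfer
        - (cur["i_bca"] + cur["i_pca"] - 2.0 * cur["i_naca"]) * CAPACITANCE / (2.0 * VC * FARADAY)
    )
    dy[4] = buf_sr * (i_up - i_rel - i_leak)
    dy[5] = buf_ss * (
        -cur["i_cal"] * CAPACITANCE / (2.0 * VSS * FARADAY)
        + i_rel * VSR / VSS
        - i_xfer * VC / VSS
    )

    dy[1] = -(cur["i_na"] + cur["i_bna"] + 3.0 * cur["i_nak"] + 3.0 * cur["i_naca"]) \
        * CAPACITANCE / (VC * FARADAY)
    dy[2] = -(
        i_stim + cur["i_k1"] + cur["i_to"] + cur["i_kr"] + cur["i_ks"]
        - 2.0 * cur["i_nak"] + cur["i_pk"] + cur["i_katp"]
    ) * CAPACITANCE / (VC * FARADAY)
    return dy
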