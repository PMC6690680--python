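"""Fixed-step Rush–Larsen / operator-splitting kernels for TP06.

The eleven voltage gates are advanced exactly for frozen V (Rush–Larsen),
with their steady states and per-step decay factors pre-tabulated on a fine
membrane-potential grid; membrane potential and concentrations use forward
Euler.  The cable kernel adds a Lie split with an explicit central-difference
diffusion step and no-flux boundaries.  These kernels are validated against
the reference NumPy right-hand side in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import _tp06 as tp

# membrane-potential lookup grid
VMIN, VMAX, DV = -150.0, 100.0, 0.02
NV = int(round((VMAX - VMIN) / DV)) + 1
# (V - EK) grid for the inward-rectifier gate
XMIN, XMAX, DX = -120.0, 260.0, 0.02
NX = int(round((XMAX - XMIN) / DX)) + 1

_table_cache: dict = {}


def build_tables(dt: float):
    """Pre-tabulated gate and current voltage factors for step size ``dt``.

    Returns (ginf, gedt, cur, reck1): gate steady states, per-step gate
    decay factors exp(-dt/tau), the six V-dependent current factors
    (ICaL c1, c2; INaK rec; NCX e1, e2; IpK rec) and the IK1 rectifier
    factor tabulated against V - EK.
    """
    key = round(float(dt), 9)
    if key in _table_cache:
        return _table_cache[key]
    v = np.linspace(VMIN, VMAX, NV)
    inf, tau = tp.gate_inf_tau(v)
    gedt = np.exp(-dt / tau)
    c1, c2 = tp.ical_factors(v)
    cur = np.stack([c1, c2, tp.inak_vfactor(v), *tp.inaca_factors(v), tp.ipk_rec(v)])
    x = np.linspace(XMIN, XMAX, NX)
    reck1 = tp.rec_k1(x)
    out = (
        np.ascontiguousarray(inf),
        np.ascontiguousarray(gedt),
        np.ascontiguousarray(cur),
        np.ascontiguousarray(reck1),
    )
    _table_cache[key] = out
    return out


# constants re-exported as plain floats for the jitted code
_RTONF = tp.RTONF
_NAO, _CAO, _KO_N = tp.NAO, tp.CAO, tp.KO_CONTROL
_CAP, _VC, _VSR, _VSS, _F = tp.CAPACITANCE, tp.VC, tp.VSR, tp.VSS, tp.FARADAY
_BUFC, _KBUFC = tp.BUFC, tp.KBUFC
_BUFSR, _KBUFSR = tp.BUFSR, tp.KBUFSR
_BUFSS, _KBUFSS = tp.BUFSS, tp.KBUFSS
_VMAXUP, _KUP = tp.VMAXUP, tp.KUP
_VREL, _VLEAK, _VXFER = tp.VREL, tp.VLEAK, tp.VXFER
_K1P, _K2P, _K3, _K4 = tp.K1P, tp.K2P, tp.K3, tp.K4
_EC, _MAXSR, _MINSR = tp.EC, tp.MAXSR, tp.MINSR
_GNA, _GKR, _GKS, _GK1, _GTO = tp.G_NA, tp.G_KR, tp.G_KS, tp.G_K1, tp.G_TO
_GPK, _GPCA, _GBNA, _GBCA = tp.G_PK, tp.G_PCA, tp.G_BNA, tp.G_BCA
_PNAK, _KNACA = tp.P_NAK, tp.K_NACA
_PKNA, _KMK, _KMNA = tp.PKNA, tp.KM_K, tp.KM_NA
_KMNAI, _KMCA, _KSAT, _ANACA = tp.KM_NAI, tp.KM_CA, tp.KSAT, tp.ALPHA_NACA
_KPCA = tp.KP_CA
_GKATP = tp.G_KATP


@njit(cache=True, fastmath=True, inline="always")
def _step(y, dt, i_stim, scales, ko, sqrt_ko, katp_fac, nak_ko, f_inhib,
          ginf, gedt, cur, reck1):
    """Advance one cell state in place by one step of length dt."""
    v = y[0]
    nai = y[1]
    ki = y[2]
    cai = y[3]
    casr = y[4]
    cass = y[5]

    # table lookup weights
    fv = (v - VMIN) / DV
    if fv < 0.0:
        fv = 0.0
    elif fv > NV - 1.001:
        fv = NV - 1.001
    i0 = int(fv)
    w = fv - i0

    # Rush–Larsen gate update
    for g in range(11):
        inf = ginf[g, i0] + w * (ginf[g, i0 + 1] - ginf[g, i0])
        e = gedt[g, i0] + w * (gedt[g, i0 + 1] - gedt[g, i0])
        y[6 + g] = inf + (y[6 + g] - inf) * e

    c1 = cur[0, i0] + w * (cur[0, i0 + 1] - cur[0, i0])
    c2 = cur[1, i0] + w * (cur[1, i0 + 1] - cur[1, i0])
    nak_rec = cur[2, i0] + w * (cur[2, i0 + 1] - cur[2, i0])
    e1 = cur[3, i0] + w * (cur[3, i0 + 1] - cur[3, i0])
    e2 = cur[4, i0] + w * (cur[4, i0 + 1] - cur[4, i0])
    pk_rec = cur[5, i0] + w * (cur[5, i0 + 1] - cur[5, i0])

    ek = _RTONF * np.log(ko / ki)
    ena = _RTONF * np.log(_NAO / nai)
    eks = _RTONF * np.log((ko + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTONF * np.log(_CAO / cai)

    x = v - ek
    fx = (x - XMIN) / DX
    if fx < 0.0:
        fx = 0.0
    elif fx > NX - 1.001:
        fx = NX - 1.001
    ix = int(fx)
    wx = fx - ix
    rk1 = reck1[ix] + wx * (reck1[ix + 1] - reck1[ix])

    m = y[6]
    h = y[7]
    j = y[8]
    i_na = f_inhib * scales[0] * _GNA * m * m * m * h * j * (v - ena)
    dff = y[14] * y[15] * y[16] * y[17]
    i_cal = f_inhib * scales[1] * dff * (c1 * cass - c2)
    i_kr = scales[2] * _GKR * sqrt_ko * y[9] * y[10] * (v - ek)
    i_ks = scales[3] * _GKS * y[11] * y[11] * (v - eks)
    i_k1 = scales[4] * _GK1 * sqrt_ko * rk1 * (v - ek)
    i_to = scales[5] * _GTO * y[12] * y[13] * (v - ek)
    i_pk = scales[6] * _GPK * pk_rec * (v - ek)
    i_pca = scales[7] * _GPCA * cai / (_KPCA + cai)
    i_bna = scales[8] * _GBNA * (v - ena)
    i_bca = scales[9] * _GBCA * (v - eca)
    i_nak = scales[10] * _PNAK * nak_ko * (nai / (nai + _KMNA)) * nak_rec
    i_naca = scales[11] * _KNACA * (
        e1 * nai * nai * nai * _CAO - e2 * _NAO * _NAO * _NAO * cai * _ANACA
    ) / ((_KMNAI ** 3 + _NAO ** 3) * (_KMCA + _CAO) * (1.0 + _KSAT * e2))
    i_katp = katp_fac * (v - ek)

    # SR calcium handling
    kcasr = _MAXSR - (_MAXSR - _MINSR) / (1.0 + (_EC / casr) ** 2)
    k1 = _K1P / kcasr
    k2 = _K2P * kcasr
    rbar = y[18]
    # exact exponential update of the linear RyR adaptation variable
    rrate = k2 * cass + _K4
    rinf = _K4 / rrate
    y[18] = rinf + (rbar - rinf) * np.exp(-dt * rrate)
    o_rel = k1 * cass * cass * rbar / (_K3 + k1 * cass * cass)
    i_rel = _VREL * o_rel * (casr - cass)
    i_leak = _VLEAK * (casr - cai)
    i_up = _VMAXUP / (1.0 + (_KUP / cai) ** 2)
    i_xfer = _VXFER * (cass - cai)

    buf_c = 1.0 / (1.0 + _BUFC * _KBUFC / ((cai + _KBUFC) * (cai + _KBUFC)))
    buf_sr = 1.0 / (1.0 + _BUFSR * _KBUFSR / ((casr + _KBUFSR) * (casr + _KBUFSR)))
    buf_ss = 1.0 / (1.0 + _BUFSS * _KBUFSS / ((cass + _KBUFSS) * (cass + _KBUFSS)))

    y[3] = cai + dt * buf_c * (
        (i_leak - i_up) * _VSR / _VC
        + i_xfer
        - (i_bca + i_pca - 2.0 * i_naca) * _CAP / (2.0 * _VC * _F)
    )
    y[4] = casr + dt * buf_sr * (i_up - i_rel - i_leak)
    y[5] = cass + dt * buf_ss * (
        -i_cal * _CAP / (2.0 * _VSS * _F) + i_rel * _VSR / _VSS - i_xfer * _VC / _VSS
    )

    # fCass gate (Rush–Larsen with Cass-dependent kinetics)
    csq = (cass / 0.05) ** 2
    fc_inf = 0.6 / (1.0 + csq) + 0.4
    tau_fc = 80.0 / (1.0 + csq) + 2.0
    y[17] = fc_inf + (y[17] - fc_inf) * np.exp(-dt / tau_fc)

    y[1] = nai + dt * (-(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * _CAP / (_VC * _F))
    y[2] = ki + dt * (
        -(i_stim + i_k1 + i_to + i_kr + i_ks - 2.0 * i_nak + i_pk + i_katp)
        * _CAP / (_VC * _F)
    )
    i_ion = (
        i_na + i_cal + i_to + i_kr + i_ks + i_k1 + i_naca + i_nak
        + i_pca + i_pk + i_bna + i_bca + i_katp
    )
    y[0] = v + dt * (-(i_ion + i_stim))

    # positivity floors keep the logarithms defined if a pathological
    # parameter draw drives a concentration to zero
    if y[3] < 1e-9:
        y[3] = 1e-9
    if y[4] < 1e-9:
        y[4] = 1e-9
    if y[5] < 1e-9:
        y[5] = 1e-9
    if y[1] < 1e-3:
        y[1] = 1e-3
    if y[2] < 1e-3:
        y[2] = 1e-3


@njit(cache=True, fastmath=True)
def run_beats(y, n_beats, cl, dt, scales, ko, f_katp, f_inhib,
              stim_amp, stim_dur, ginf, gedt, cur, reck1):
    """Pace a single cell for n_beats cycles; state updated in place."""
    sqrt_ko = np.sqrt(ko / _KO_N)
    katp_fac = f_katp * _GKATP * (ko / _KO_N) ** 0.24
    nak_ko = ko / (ko + _KMK)
    n_steps = int(round(cl / dt))
    n_stim = int(round(stim_dur / dt))
    for _ in range(n_beats):
        for k in range(n_steps):
            i_stim = stim_amp if k < n_stim else 0.0
            _step(y, dt, i_stim, scales, ko, sqrt_ko, katp_fac, nak_ko,
                  f_inhib, ginf, gedt, cur, reck1)


@njit(cache=True, fastmath=True)
def run_beat_record(y, cl, dt, scales, ko, f_katp, f_inhib,
                    stim_amp, stim_dur, ginf, gedt, cur, reck1):
    """Run one cycle recording V at every step; returns the V samples."""
    sqrt_ko = np.sqrt(ko / _KO_N)
    katp_fac = f_katp * _GKATP * (ko / _KO_N) ** 0.24
    nak_ko = ko / (ko + _KMK)
    n_steps = int(round(cl / dt))
    n_stim = int(round(stim_dur / dt))
    v_out = np.empty(n_steps + 1)
    v_out[0] = y[0]
    for k in range(n_steps):
        i_stim = stim_amp if k < n_stim else 0.0
        _step(y, dt, i_stim, scales, ko, sqrt_ko, katp_fac, nak_ko,
              f_inhib, ginf, gedt, cur, reck1)
        v_out[k + 1] = y[0]
    return v_out


@njit(cache=True, fastmath=True)
def run_cable(state, n_beats, cl, dt, scales, ko_n, fkatp_n, finhib_n,
              d_coeff, dl, stim_amp, stim_dur, n_stim_nodes,
              save_last, save_every, ginf, gedt, cur, reck1):
    """Operator-split cable integration; state is (n_nodes, 19), in place.

    Reaction step per node (Rush–Larsen/Euler) followed by an explicit
    central-difference diffusion step on V with no-flux boundaries.
    Returns the V field of the last beat sampled every ``save_every`` steps
    (shape (n_samples, n_nodes)); when ``save_last`` is False an empty
    array is returned.
    """
    nn = state.shape[0]
    sqrt_ko = np.empty(nn)
    katp_fac = np.empty(nn)
    nak_ko = np.empty(nn)
    for i in range(nn):
        sqrt_ko[i] = np.sqrt(ko_n[i] / _KO_N)
        katp_fac[i] = fkatp_n[i] * _GKATP * (ko_n[i] / _KO_N) ** 0.24
        nak_ko[i] = ko_n[i] / (ko_n[i] + _KMK)

    n_steps = int(round(cl / dt))
    n_stim = int(round(stim_dur / dt))
    alpha = d_coeff * dt / (dl * dl)
    v_new = np.empty(nn)

    n_samp = n_steps // save_every + 1
    if save_last:
        field = np.empty((n_samp, nn))
    else:
        field = np.empty((0, nn))

    for beat in range(n_beats):
        recording = save_last and beat == n_beats - 1
        if recording:
            for i in range(nn):
                field[0, i] = state[i, 0]
        row = 1
        for k in range(n_steps):
            stim_on = k < n_stim
            for i in range(nn):
                i_stim = stim_amp if (stim_on and i < n_stim_nodes) else 0.0
                _step(state[i], dt, i_stim, scales, ko_n[i], sqrt_ko[i],
                      katp_fac[i], nak_ko[i], finhib_n[i],
                      ginf, gedt, cur, reck1)
            # diffusion on V, no-flux boundaries
            v_new[0] = state[0, 0] + alpha * 2.0 * (state[1, 0] - state[0, 0])
            for i in range(1, nn - 1):
                v_new[i] = state[i, 0] + alpha * (
                    state[i - 1, 0] - 2.0 * state[i, 0] + state[i + 1, 0]
                )
            v_new[nn - 1] = state[nn - 1, 0] + alpha * 2.0 * (
                state[nn - 2, 0] - state[nn - 1, 0]
            )
            for i in range(nn):
                state[i, 0] = v_new[i]
            if recording and (k + 1) % save_every == 0:
                for i in range(nn):
                    field[row, i] = state[i, 0]
                row += 1
    return field
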