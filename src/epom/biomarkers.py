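"""Action-potential and pseudo-ECG biomarker extraction.

AP biomarkers
-------------
* APA — peak membrane potential, measured with respect to zero (mV);
* RMP — membrane potential at the end of the cycle (mV);
* upstroke time — stimulus onset to peak V (ms);
* APD90 — from activation (maximum dV/dt) until V first recovers 90% of
  the peak-to-rest excursion (``repol90``, the default).  The literal
  zero-referenced reading — V crossing 10% of the APA — is available via
  ``convention="apa_fraction"``.

pECG biomarkers (six, matching the delineation sketch of a single beat):
QRS duration, QT interval, ST deviation, T-wave duration, QRS amplitude
and T-wave amplitude.  Wave onsets/ends are the instants where |phi_e|
crosses 10% of the wave's peak magnitude on the corresponding flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: spatial sampling points for conduction velocity, cm
CV_L1, CV_L2 = 0.4, 1.6

#: biomarker column order of the feature table
PECG_FEATURES = (
    "qt_interval", "st_deviation", "qrs_amplitude",
    "t_amplitude", "qrs_duration", "t_duration",
)


class DelineationError(RuntimeError):
    """The trace does not contain two distinguishable waves."""


class PropagationError(RuntimeError):
    """Activation times do not describe a forward-propagating beat."""


class BlockError(PropagationError):
    """A measurement site never activated (conduction block)."""


@dataclass(frozen=True)
class APBiomarkers:
    apd90: float  # ms; NaN when no AP was elicited
    apa: float  # mV, peak V with respect to zero
    rmp: float  # mV, V at end of cycle
    upstroke_time: float  # ms from stimulus onset to peak V


@dataclass(frozen=True)
class CVMeasure:
    cv: float  # cm/s
    at1: float  # ms, activation time at l1
    at2: float  # ms, activation time at l2
    l1: float = CV_L1
    l2: float = CV_L2


@dataclass(frozen=True)
class PECGBiomarkers:
    qrs_duration: float  # ms
    qt_interval: float  # ms
    st_deviation: float  # signal units, signed
    t_duration: float  # ms
    qrs_amplitude: float  # signal units, signed value at the QRS extremum
    t_amplitude: float  # signal units, signed value at the T extremum
    qrs_onset: float = np.nan  # ms (diagnostic)
    qrs_end: float = np.nan
    t_onset: float = np.nan
    t_end: float = np.nan

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PECG_FEATURES}


def _cross_time(t0, y0, t1, y1, thr):
    """Linear-interpolated time where |y| crosses thr between two samples."""
    if y1 == y0:
        return t0
    return t0 + (thr - y0) * (t1 - t0) / (y1 - y0)


def ap_biomarkers(trace, stim_time: float = 0.0, convention: str = "repol90") -> APBiomarkers:
    """Extract AP biomarkers from a single saved beat."""
    t = np.asarray(trace.t, dtype=float)
    v = np.asarray(trace.v, dtype=float)
    apa = float(v.max())
    rmp = float(v[-1])
    i_pk = int(np.argmax(v))
    upstroke = float(t[i_pk] - stim_time)

    dv = np.diff(v) / np.diff(t)
    t_act = float(t[int(np.argmax(dv))])

    if convention == "apa_fraction":
        thr = 0.1 * apa
    elif convention == "repol90":
        thr = apa - 0.9 * (apa - rmp)
    else:
        raise ValueError(f"unknown APD90 convention {convention!r}")

    apd90 = np.nan
    if apa > 0.0:
        tail = v[i_pk:]
        below = np.nonzero(tail < thr)[0]
        if below.size:
            k = i_pk + below[0]
            t_cross = _cross_time(t[k - 1], v[k - 1], t[k], v[k], thr) if k > 0 else t[k]
            apd90 = float(t_cross - t_act)
    return APBiomarkers(apd90=apd90, apa=apa, rmp=rmp, upstroke_time=upstroke)


def activation_time(t, v_node, threshold: float = 0.0) -> float:
    """First instant the transmembrane potential surpasses ``threshold``."""
    v_node = np.asarray(v_node, dtype=float)
    above = np.nonzero(v_node > threshold)[0]
    if not above.size:
        raise BlockError("node never activated")
    k = int(above[0])
    if k == 0:
        return float(t[0])
    return float(_cross_time(t[k - 1], v_node[k - 1], t[k], v_node[k], threshold))


def conduction_velocity(solution) -> CVMeasure:
    """Conduction velocity (l2 - l1) / (AT(l2) - AT(l1)), in cm/s.

    Activation time at each site is the first instant V surpasses 0 mV.
    """
    pos = np.asarray(solution.positions, dtype=float)
    i1 = int(np.argmin(np.abs(pos - CV_L1)))
    i2 = int(np.argmin(np.abs(pos - CV_L2)))
    at1 = activation_time(solution.t, solution.v[:, i1])
    at2 = activation_time(solution.t, solution.v[:, i2])
    if at2 <= at1:
        raise PropagationError(
            f"activation time at l2 ({at2:.2f} ms) not later than at l1 ({at1:.2f} ms)"
        )
    cv = (pos[i2] - pos[i1]) / (at2 - at1) * 1000.0  # cm/ms -> cm/s
    return CVMeasure(cv=float(cv), at1=at1, at2=at2)


def _wave_bounds(t, phi, i_lo, i_hi):
    """Locate one wave inside samples [i_lo, i_hi]: peak, onset, end.

    The peak is the extremum of |phi| inside the window; onset/end are the
    10%-of-|peak| crossings of |phi| on each flank (interpolated).  When a
    flank never drops below threshold inside the window the local minimum
    of |phi| on that flank is used instead (elevated baselines under
    severe ischemia).
    """
    a = np.abs(phi)
    i_pk = i_lo + int(np.argmax(a[i_lo:i_hi + 1]))
    peak = a[i_pk]
    thr = 0.1 * peak

    # onset: walk backwards
    i = i_pk
    onset = t[i_lo]
    while i > i_lo:
        if a[i - 1] < thr:
            onset = _cross_time(t[i - 1], a[i - 1], t[i], a[i], thr)
            break
        i -= 1
    if i == i_lo and a[i_lo] >= thr:
        seg = a[i_lo:i_pk + 1]
        onset = t[i_lo + int(np.argmin(seg))]

    # end: walk forwards
    i = i_pk
    end = t[i_hi]
    while i < i_hi:
        if a[i + 1] < thr:
            end = _cross_time(t[i], a[i], t[i + 1], a[i + 1], thr)
            break
        i += 1
    if i == i_hi and a[i_hi] >= thr:
        seg = a[i_pk:i_hi + 1]
        end = t[i_pk + int(np.argmin(seg))]

    return i_pk, float(onset), float(end)


def _tangent_bounds(t, phi, i_lo, i_hi):
    """T-wave bounds by the tangent method, robust to baseline drift.

    The slow decline of the plateau produces a drifting baseline under the
    T wave, so a fixed 10%-of-peak threshold dates the onset far too early
    on long-plateau models.  Instead, the tangent at the steepest point of
    each flank is intersected with the local baseline (the flattest point
    of the preceding segment for the onset; the late-diastolic level for
    the end) — the standard T-boundary construction in ECG delineation.
    """
    seg = phi[i_lo:i_hi + 1]
    ts = t[i_lo:i_hi + 1]
    # T extremum relative to the late-diastolic level
    base_end = float(np.median(seg[-max(3, seg.size // 10):]))
    i_pk = int(np.argmax(np.abs(seg - base_end)))
    if i_pk == 0 or i_pk >= seg.size - 1:
        raise DelineationError("T extremum at the edge of its search window")
    d = np.gradient(seg, ts)
    sign = 1.0 if seg[i_pk] >= base_end else -1.0

    # monotone run entering the extremum (walking backwards the signal
    # moves away from the extremum monotonically)
    i = i_pk
    while i > 0 and sign * (seg[i - 1] - seg[i]) <= 0.0:
        i -= 1
    if i == i_pk:
        raise DelineationError("no entering T flank found")
    i_s1 = i + int(np.argmax(np.abs(d[i:i_pk])))
    # local baseline: the flattest point of the segment preceding the flank
    i_flat = int(np.argmin(np.abs(d[i:i_s1 + 1]))) + i
    base_on = seg[i_flat]
    t_on = ts[i_s1] + (base_on - seg[i_s1]) / d[i_s1]
    t_on = float(np.clip(t_on, ts[0], ts[i_pk]))

    # monotone recovery run after the extremum
    i = i_pk
    while i < seg.size - 1 and sign * (seg[i + 1] - seg[i]) <= 0.0:
        i += 1
    if i == i_pk:
        raise DelineationError("no recovery T flank found")
    i_s2 = i_pk + int(np.argmax(np.abs(d[i_pk + 1:i + 1]))) + 1
    t_end = ts[i_s2] + (base_end - seg[i_s2]) / d[i_s2]
    t_end = float(np.clip(t_end, ts[i_pk], ts[-1]))
    return i_lo + i_pk, t_on, t_end


def delineate_pecg(trace, stim_time: float = 0.0, qrs_window: float = 100.0,
                   t_gap: float = 5.0, t_method: str = "tangent") -> PECGBiomarkers:
    """Delineate one pseudo-ECG beat into QRS complex and T wave.

    The QRS complex is the dominant deflection within ``qrs_window`` ms of
    the stimulus; the T wave is the dominant deflection after it.  QRS
    boundaries are 10%-of-peak crossings of |phi_e| on each flank, so
    delineation is invariant to uniform amplitude scaling.  T-wave
    boundaries use the tangent method by default (see
    :func:`_tangent_bounds`); ``t_method="threshold"`` applies the same
    10%-of-peak crossing rule as the QRS instead.
    """
    t = np.asarray(trace.t, dtype=float)
    phi = np.asarray(trace.phi, dtype=float)
    if t.ndim != 1 or t.size != phi.size:
        raise ValueError("trace time grid and samples must be 1-D and equal length")
    if not np.any(np.abs(phi) > 0.0):
        raise DelineationError("trace is identically zero")

    n = t.size
    i_q_hi = int(np.searchsorted(t, stim_time + qrs_window))
    i_q_hi = min(max(i_q_hi, 2), n - 1)
    i_q_lo = int(np.searchsorted(t, stim_time))

    i_qpk, q_onset, q_end = _wave_bounds(t, phi, i_q_lo, i_q_hi)
    qrs_amp = float(phi[i_qpk])
    if abs(qrs_amp) == 0.0:
        raise DelineationError("no QRS deflection found")

    i_t_lo = int(np.searchsorted(t, q_end + t_gap))
    if i_t_lo >= n - 2:
        raise DelineationError("no samples after the QRS complex")
    if t_method == "tangent":
        i_tpk, t_onset, t_end = _tangent_bounds(t, phi, i_t_lo, n - 1)
    elif t_method == "threshold":
        i_tpk, t_onset, t_end = _wave_bounds(t, phi, i_t_lo, n - 1)
    else:
        raise ValueError(f"unknown T-boundary method {t_method!r}")
    t_amp = float(phi[i_tpk])
    if abs(t_amp) < 1e-12 * abs(qrs_amp):
        raise DelineationError("no distinguishable T wave")
    t_onset = max(t_onset, q_end)

    st_mid = 0.5 * (q_end + t_onset)
    st_dev = float(np.interp(st_mid, t, phi))

    return PECGBiomarkers(
        qrs_duration=float(q_end - q_onset),
        qt_interval=float(t_end - q_onset),
        st_deviation=st_dev,
        t_duration=float(t_end - t_onset),
        qrs_amplitude=qrs_amp,
        t_amplitude=t_amp,
        qrs_onset=float(q_onset), qrs_end=float(q_end),
        t_onset=float(t_onset), t_end=float(t_end),
    )


def ratio_of_change(control: PECGBiomarkers, ischemic: PECGBiomarkers,
                    floor_rel: float = 1e-6) -> dict:
    """Per-biomarker ratio of change b' = b_ischemic / b_control.

    b' = 1 whenever the ischemic value equals the control value.  A
    control biomarker whose magnitude is below ``floor_rel`` times the
    control QRS amplitude (the near-isoelectric ST segment of healthy
    cables) is degenerate as a denominator; there the signed difference
    is reported instead and flagged in the ``"_substituted"`` entry.
    """
    floor = floor_rel * abs(control.qrs_amplitude)
    out = {}
    substituted = []
    for name in PECG_FEATURES:
        b_c = getattr(control, name)
        b_i = getattr(ischemic, name)
        if abs(b_c) <= floor:
            out[name] = b_i - b_c
            substituted.append(name)
        else:
            out[name] = b_i / b_c
    out["_substituted"] = tuple(substituted)
    return out
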