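"""Pseudo-ECG at a virtual unipolar probe beyond the cable end.

The extracellular potential is the convolution of the membrane-potential
gradient with the gradient of the 1/distance kernel,

    phi_e(l') = A * integral (-dV/dl) d/dl[1 / |l - l'|] dl ,

evaluated over an interior node window (cells 15 to 85 by default) to keep
stimulus and boundary artifacts out of the signal.  In 1D, with the probe
at l' beyond the cable end, d/dl[1/(l'-l)] = 1/(l'-l)^2, so a depolarization
front propagating toward the probe produces a positive deflection.  The
spatial gradient uses central differences and the integral the trapezoidal
rule.  The amplitude constant A is 1: the signal scale carries no
information here (it is a property of the torso, not the fiber).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cell_model import InvalidParameterError


@dataclass(frozen=True)
class ProbeConfig:
    position: float = 4.0  # cm, 2 cm beyond the cable end
    amplitude: float = 1.0  # dimensionless A
    window: tuple = (15, 85)  # inclusive node indices used for the integral


@dataclass
class PECGTrace:
    t: np.ndarray  # ms
    phi: np.ndarray  # signal units
    meta: dict = field(default_factory=dict)


def compute_pecg(solution, probe: ProbeConfig = ProbeConfig()) -> PECGTrace:
    """Pseudo-ECG of a cable solution at the virtual probe."""
    pos = np.asarray(solution.positions, dtype=float)
    if pos.min() <= probe.position <= pos.max():
        raise InvalidParameterError(
            "probe inside the cable: the 1/|l - l'| kernel is singular"
        )
    lo, hi = probe.window
    if not (0 < lo < hi < pos.size - 1):
        raise InvalidParameterError("integration window must be strictly interior")

    x = pos[lo:hi + 1]
    v = solution.v[:, lo:hi + 1]  # (time, node)
    dl = pos[1] - pos[0]
    # central differences on the interior of the window
    dvdl = np.empty_like(v)
    dvdl[:, 1:-1] = (v[:, 2:] - v[:, :-2]) / (2.0 * dl)
    dvdl[:, 0] = (v[:, 1] - v[:, 0]) / dl
    dvdl[:, -1] = (v[:, -1] - v[:, -2]) / dl
    # d/dl [1/|l - l'|], signed derivative with respect to the source point
    r = probe.position - x
    kernel = np.sign(r) / r ** 2
    phi = probe.amplitude * np.trapezoid(-dvdl * kernel, x, axis=1)
    return PECGTrace(
        t=np.asarray(solution.t, dtype=float).copy(), phi=phi,
        meta=dict(getattr(solution, "meta", {}), probe=probe.position),
    )
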