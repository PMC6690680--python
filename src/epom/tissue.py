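"""1D homogeneous cable of TP06 cells with a regionally-ischemic center.

The monodomain cable  dV/dt = D d2V/dl2 - I_ion + I_stim  is solved by the
method of lines: second-order central differences in space, no-flux
boundaries, and (by default) an operator-split fixed-step scheme that
advances the reaction term with the Rush–Larsen kernel and the diffusion
term explicitly.  Geometry follows the study setup: length 2 cm, node
spacing 0.02 cm, stimulation at l = 0, 30 beats at CL 600 ms with the
last beat saved.

The diffusivity default is 1.171e-3 cm^2/ms.  (Expressed in cm^2/s this
coefficient would yield ~2 cm/s conduction, thirty-fold below the ~60 cm/s
a healthy human ventricular fiber conducts at; per-ms units reproduce the
physiological scale and are stated explicitly here.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cell_model import (
    IschemiaSpec,
    InvalidParameterError,
    NumericalError,
    PacingProtocol,
    ParameterSet,
    initial_state,
)

#: transition-zone length at either end of the ischemic region, cm
TRANSITION = 0.1


class ConfigurationError(RuntimeError):
    """Solver/stimulus settings failed to elicit expected propagation."""


@dataclass(frozen=True)
class CableGeometry:
    length: float = 2.0  # cm
    dl: float = 0.02  # cm
    diffusivity: float = 1.171e-3  # cm^2/ms

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dl)) + 1

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_nodes)


@dataclass
class CableSolution:
    t: np.ndarray  # ms, one saved cycle
    v: np.ndarray  # mV, (time, node)
    positions: np.ndarray  # cm
    cl: float
    n_beats: int
    profile: dict = field(default_factory=dict)  # per-node ko/f_katp/f_inhib
    meta: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None  # (node, 19)


def region_profile(preset: IschemiaSpec, zone_size: float,
                   geometry: CableGeometry = CableGeometry()) -> dict:
    """Per-node ischemia parameters for a centered ischemic region.

    Nodes inside the central zone carry the full preset; a ``TRANSITION``
    band at either end ramps f_katp, f_inhib and Ko linearly back to the
    control values; everything else is control tissue.  Transitions are
    truncated at the cable ends, so a zone as long as the cable makes the
    whole fiber ischemic.
    """
    if zone_size <= 0.0:
        raise InvalidParameterError("zone size must be positive")
    x = geometry.positions
    c = geometry.length / 2.0
    half = zone_size / 2.0
    # fraction of the ischemic preset at each node: 1 inside the zone,
    # linear within the transitions, 0 outside
    dist = np.abs(x - c)
    frac = np.clip((half + TRANSITION - dist) / TRANSITION, 0.0, 1.0)
    ctrl = IschemiaSpec.control()
    return {
        "f_katp": ctrl.f_katp + frac * (preset.f_katp - ctrl.f_katp),
        "f_inhib": ctrl.f_inhib + frac * (preset.f_inhib - ctrl.f_inhib),
        "ko": ctrl.ko + frac * (preset.ko - ctrl.ko),
        "severity": preset.label,
        "zone_size": float(zone_size),
    }


def uniform_profile(spec: IschemiaSpec,
                    geometry: CableGeometry = CableGeometry()) -> dict:
    """Whole-cable profile at a single severity (control or full ischemia)."""
    n = geometry.n_nodes
    return {
        "f_katp": np.full(n, spec.f_katp),
        "f_inhib": np.full(n, spec.f_inhib),
        "ko": np.full(n, spec.ko),
        "severity": spec.label,
        "zone_size": float(geometry.length) if spec.label != "control" else 0.0,
    }


def simulate_cable(
    params: ParameterSet,
    profile: dict,
    geometry: CableGeometry = CableGeometry(),
    protocol: PacingProtocol = PacingProtocol(cl=600.0, n_beats=30),
    *,
    dt: float = 0.02,
    save_dt: float = 0.5,
    stim_nodes: int = 3,
    initial: np.ndarray | None = None,
    expect_propagation: bool = False,
) -> CableSolution:
    """Integrate the cable and return the last beat as a (time, node) field.

    ``initial`` may be a single-cell state (replicated across the cable,
    the warm-start path) or a full (node, 19) field.  The CFL-stable
    explicit diffusion step requires D*dt/dl^2 < 0.5, checked here.
    """
    n = geometry.n_nodes
    alpha = geometry.diffusivity * dt / geometry.dl ** 2
    if alpha >= 0.5:
        raise InvalidParameterError(
            f"explicit diffusion unstable: D*dt/dl^2 = {alpha:.3f} >= 0.5"
        )
    if initial is None:
        state = np.tile(initial_state(), (n, 1))
    else:
        initial = np.asarray(initial, dtype=float)
        state = np.tile(initial, (n, 1)) if initial.ndim == 1 else initial.copy()
    if state.shape != (n, _kernels.tp.N_STATE):
        raise InvalidParameterError("initial state shape does not match geometry")

    gi, ge, cu, rk = _kernels.build_tables(dt)
    save_every = max(1, int(round(save_dt / dt)))
    field_v = _kernels.run_cable(
        state, protocol.n_beats, protocol.cl, dt, params.scales,
        np.asarray(profile["ko"], dtype=float),
        np.asarray(profile["f_katp"], dtype=float),
        np.asarray(profile["f_inhib"], dtype=float),
        geometry.diffusivity, geometry.dl,
        protocol.stim_amplitude, protocol.stim_duration, stim_nodes,
        True, save_every, gi, ge, cu, rk,
    )
    if not np.all(np.isfinite(field_v)):
        raise NumericalError("non-finite field in cable solution", state=state)
    t = np.arange(field_v.shape[0]) * dt * save_every
    sol = CableSolution(
        t=t, v=field_v, positions=geometry.positions,
        cl=protocol.cl, n_beats=protocol.n_beats,
        profile={k: v for k, v in profile.items()},
        meta={"model_id": params.id, "severity": profile.get("severity", "control"),
              "zone_size": profile.get("zone_size", 0.0), "dt": dt},
        final_state=state,
    )
    if expect_propagation and not np.any(sol.v[:, -1] > 0.0):
        raise ConfigurationError(
            "no activation at the distal cable end; check stimulus and diffusivity"
        )
    return sol
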