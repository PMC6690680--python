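"""Single-cell TP06 electrophysiology with an acute-ischemia overlay.

The ischemia overlay has three components, each graded by severity:

* hyperkalemia — elevated extracellular potassium ``ko`` enters every
  K+-dependent reversal potential and current;
* acidosis — the fast sodium and L-type calcium currents are multiplied
  by the inhibition constant ``f_inhib``;
* hypoxia — an ATP-sensitive potassium current
  ``I_KATP = f_katp * G_KATP * (Ko/Ko_n)^0.24 * (V - EK)`` is added.

Severity presets: control (0, 1, 5.4 mM), mild (0.1, 0.875, 6.25 mM) and
severe (0.2, 0.75, 9.0 mM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels, _tp06
from ._tp06 import (  # noqa: F401  (re-exported as the module's public surface)
    G_KATP,
    KO_CONTROL,
    N_STATE,
    PARAM_NAMES,
    RTONF,
    baseline_scales,
    currents,
    initial_state,
    rhs,
)


class InvalidParameterError(ValueError):
    """A model, protocol or ischemia parameter is out of its valid range."""


class NumericalError(RuntimeError):
    """The integrator produced a non-finite state; carries a snapshot."""

    def __init__(self, message: str, state: np.ndarray | None = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class ParameterSet:
    """Dimensionless multipliers on the TP06 maximal conductances and
    peak currents, one per entry of :data:`PARAM_NAMES`; all in [0, 2].
    The all-ones set reproduces the published baseline model."""

    scales: np.ndarray
    id: str = "baseline"

    def __post_init__(self):
        scales = np.asarray(self.scales, dtype=float)
        if scales.shape != (len(PARAM_NAMES),):
            raise InvalidParameterError(
                f"expected {len(PARAM_NAMES)} scale factors, got {scales.shape}"
            )
        if np.any(scales < 0.0) or np.any(scales > 2.0):
            raise InvalidParameterError("scale factors must lie in [0, 2]")
        object.__setattr__(self, "scales", scales)

    @classmethod
    def baseline(cls, id: str = "baseline") -> "ParameterSet":
        return cls(scales=baseline_scales(), id=id)

    def to_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(PARAM_NAMES, self.scales)}
        d["id"] = self.id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(
            scales=np.array([d[name] for name in PARAM_NAMES], dtype=float),
            id=str(d.get("id", "unnamed")),
        )


@dataclass(frozen=True)
class IschemiaSpec:
    """Severity parameters of the acute-ischemia overlay."""

    f_katp: float = 0.0
    f_inhib: float = 1.0
    ko: float = KO_CONTROL
    label: str = "control"

    #: control extracellular potassium, mM
    KO_N = KO_CONTROL
    #: ATP-sensitive channel conductance, mS/uF
    G_KATP = G_KATP

    def __post_init__(self):
        if self.ko <= 0.0:
            raise InvalidParameterError("extracellular potassium must be positive")
        if self.f_katp < 0.0 or not (0.0 < self.f_inhib <= 1.0):
            raise InvalidParameterError("f_katp >= 0 and 0 < f_inhib <= 1 required")

    @classmethod
    def control(cls) -> "IschemiaSpec":
        return cls(0.0, 1.0, KO_CONTROL, "control")

    @classmethod
    def mild(cls) -> "IschemiaSpec":
        return cls(0.1, 0.875, 6.25, "mild")

    @classmethod
    def severe(cls) -> "IschemiaSpec":
        return cls(0.2, 0.75, 9.0, "severe")

    @classmethod
    def preset(cls, label: str) -> "IschemiaSpec":
        try:
            return {"control": cls.control, "mild": cls.mild, "severe": cls.severe}[label]()
        except KeyError:
            raise InvalidParameterError(f"unknown severity preset {label!r}") from None

    def to_dict(self) -> dict:
        return {"f_katp": self.f_katp, "f_inhib": self.f_inhib,
                "ko": self.ko, "label": self.label}


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic stimulation protocol.

    The stimulus is a rectangular current pulse delivered at the start of
    every cycle; the default −52 A/F for 1 ms is the conventional TP06
    suprathreshold stimulus.
    """

    cl: float = 600.0  # cycle length, ms
    n_beats: int = 200
    stim_amplitude: float = -52.0  # A/F
    stim_duration: float = 1.0  # ms
    save: str = "last"  # "last" or "all"

    def __post_init__(self):
        if not (self.cl > self.stim_duration > 0.0):
            raise InvalidParameterError("require CL > stimulus duration > 0")
        if self.n_beats < 1:
            raise InvalidParameterError("n_beats must be >= 1")
        if self.save not in ("last", "all"):
            raise InvalidParameterError("save policy must be 'last' or 'all'")


@dataclass
class APTrace:
    """One saved action-potential cycle on a uniform time grid."""

    t: np.ndarray  # ms, starting at 0 (stimulus onset)
    v: np.ndarray  # mV
    cl: float
    meta: dict = field(default_factory=dict)
    #: full model state at the end of the saved beat (for warm starts)
    final_state: np.ndarray | None = None


def ikatp_current(spec: IschemiaSpec, v, ek):
    """ATP-sensitive potassium current density, A/F.

    ``f_katp * G_KATP * (Ko / Ko_n)^0.24 * (V - EK)``; at control
    potassium the concentration factor is exactly 1.
    """
    if spec.ko <= 0.0:
        raise InvalidParameterError("extracellular potassium must be positive")
    return spec.f_katp * G_KATP * (spec.ko / KO_CONTROL) ** 0.24 * (np.asarray(v) - ek)


def nernst_k(ko: float, ki: float) -> float:
    """Potassium reversal potential (mV) at 310 K."""
    return RTONF * np.log(ko / ki)


def cell_rhs(t, y, params: ParameterSet, spec: IschemiaSpec, i_stim: float = 0.0):
    """Reference TP06 time derivative including the ischemia overlay."""
    dy = rhs(t, y, params.scales, spec.ko, spec.f_katp, spec.f_inhib, i_stim)
    if not np.all(np.isfinite(dy)):
        raise NumericalError("non-finite derivative", state=np.array(y))
    return dy


def _pace_rl(params, spec, protocol, state, dt_prepace, dt_beat):
    gi_c, ge_c, cu, rk = _kernels.build_tables(dt_prepace)
    gi_f, ge_f, _, _ = _kernels.build_tables(dt_beat)
    y = state.copy()
    if protocol.n_beats > 1:
        _kernels.run_beats(
            y, protocol.n_beats - 1, protocol.cl, dt_prepace, params.scales,
            spec.ko, spec.f_katp, spec.f_inhib,
            protocol.stim_amplitude, protocol.stim_duration, gi_c, ge_c, cu, rk,
        )
    v = _kernels.run_beat_record(
        y, protocol.cl, dt_beat, params.scales,
        spec.ko, spec.f_katp, spec.f_inhib,
        protocol.stim_amplitude, protocol.stim_duration, gi_f, ge_f, cu, rk,
    )
    t = np.arange(v.size) * dt_beat
    return t, v, y


def _pace_lsoda(params, spec, protocol, state, rtol, atol):
    y = state.copy()
    t_beat = None
    v_beat = None
    for beat in range(protocol.n_beats):
        last = beat == protocol.n_beats - 1
        # stimulus interval, then the remainder of the cycle
        sol1 = solve_ivp(
            cell_rhs, (0.0, protocol.stim_duration), y, method="LSODA",
            args=(params, spec, protocol.stim_amplitude), rtol=rtol, atol=atol,
            dense_output=last,
        )
        y = sol1.y[:, -1]
        sol2 = solve_ivp(
            cell_rhs, (protocol.stim_duration, protocol.cl), y, method="LSODA",
            args=(params, spec, 0.0), rtol=rtol, atol=atol, dense_output=last,
        )
        y = sol2.y[:, -1]
        if not (sol1.success and sol2.success):
            raise NumericalError(f"LSODA failed on beat {beat}", state=y)
        if last:
            t1 = np.arange(0.0, protocol.stim_duration, 0.02)
            t2 = np.arange(protocol.stim_duration, protocol.cl + 1e-9, 0.02)
            t_beat = np.concatenate([t1, t2])
            v_beat = np.concatenate(
                [sol1.sol(t1)[0], sol2.sol(t2)[0]]
            )
    return t_beat, v_beat, y


def pace_cell(
    params: ParameterSet,
    spec: IschemiaSpec,
    protocol: PacingProtocol,
    *,
    solver: str = "rl",
    dt_prepace: float = 0.1,
    dt_beat: float = 0.02,
    output_dt: float = 0.1,
    rtol: float = 1e-3,
    atol: float = 1e-6,
    initial: np.ndarray | None = None,
    check_alternans: bool = False,
) -> APTrace:
    """Pace a single cell to steady state and return the last saved beat.

    ``solver="rl"`` (default) uses the fixed-step Rush–Larsen kernel with a
    coarse pre-pacing step and a fine step for the saved beat;
    ``solver="lsoda"`` uses the adaptive stiff integrator at the reference
    tolerances (rtol 1e-3, atol 1e-6).  The saved beat is resampled onto a
    uniform ``output_dt`` grid (0.1 ms) for biomarker extraction.

    With ``check_alternans`` the cell is paced for five further recorded
    beats and the spread of their APD90 values is written to the trace
    metadata; a beat-to-beat oscillation above 1 ms marks the trace
    non-convergent (flagged, not fatal).
    """
    state = initial_state() if initial is None else np.asarray(initial, dtype=float).copy()
    if solver == "rl":
        t, v, y = _pace_rl(params, spec, protocol, state, dt_prepace, dt_beat)
    elif solver == "lsoda":
        t, v, y = _pace_lsoda(params, spec, protocol, state, rtol, atol)
    else:
        raise InvalidParameterError(f"unknown solver {solver!r}")

    if not np.all(np.isfinite(v)):
        raise NumericalError("non-finite membrane potential in saved beat", state=y)

    grid = np.arange(0.0, protocol.cl + output_dt / 2, output_dt)
    v_grid = np.interp(grid, t, v)
    meta = {"solver": solver, "model_id": params.id, "severity": spec.label}

    if check_alternans:
        from .biomarkers import ap_biomarkers  # local import: cyclic module pair

        apds = [ap_biomarkers(APTrace(t=grid, v=v_grid, cl=protocol.cl)).apd90]
        y_probe = y.copy()
        gi, ge, cu, rk = _kernels.build_tables(dt_beat)
        for _ in range(5):
            v_b = _kernels.run_beat_record(
                y_probe, protocol.cl, dt_beat, params.scales,
                spec.ko, spec.f_katp, spec.f_inhib,
                protocol.stim_amplitude, protocol.stim_duration, gi, ge, cu, rk,
            )
            t_b = np.arange(v_b.size) * dt_beat
            apds.append(
                ap_biomarkers(APTrace(t=t_b, v=v_b, cl=protocol.cl)).apd90
            )
        swing = float(np.nanmax(np.abs(np.diff(apds))))
        meta["apd_beat_to_beat_ms"] = swing
        meta["non_convergent"] = bool(swing > 1.0)

    return APTrace(t=grid, v=v_grid, cl=protocol.cl, meta=meta, final_state=y)


def steady_state(
    params: ParameterSet,
    spec: IschemiaSpec,
    protocol: PacingProtocol,
    *,
    dt: float = 0.1,
    initial: np.ndarray | None = None,
) -> np.ndarray:
    """Full model state after ``protocol.n_beats`` of pre-pacing (no trace)."""
    gi, ge, cu, rk = _kernels.build_tables(dt)
    y = (initial_state() if initial is None else np.asarray(initial, dtype=float)).copy()
    _kernels.run_beats(
        y, protocol.n_beats, protocol.cl, dt, params.scales,
        spec.ko, spec.f_katp, spec.f_inhib,
        protocol.stim_amplitude, protocol.stim_duration, gi, ge, cu, rk,
    )
    if not np.all(np.isfinite(y)):
        raise NumericalError("non-finite state after pre-pacing", state=y)
    return y


def with_severity(spec: IschemiaSpec, label: str) -> IschemiaSpec:
    """Convenience: replace only the label (used by audit trails)."""
    return replace(spec, label=label)
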