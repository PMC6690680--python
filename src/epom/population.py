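"""Experimentally-calibrated populations of models (ePoM).

The control population is built by (1) Latin Hypercube Sampling of the
twelve conductance/peak-current multipliers in [0, 2], (2) pacing every
sampled cell for 200 beats at cycle lengths 430 ms and 600 ms and keeping
the last beat, (3) excluding unphysiological cells (APA < 0,
RMP > -64 mV, upstroke time > 10 ms, in that reporting order) and
(4) keeping only cells whose APD90 falls inside the monophasic-AP
calibration windows at *both* cycle lengths: [170, 240] ms at CL 430 and
[195, 290] ms at CL 600 (closed intervals).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from . import biomarkers as bm
from .cell_model import (
    APTrace,
    IschemiaSpec,
    InvalidParameterError,
    NumericalError,
    PacingProtocol,
    ParameterSet,
    pace_cell,
)
from ._tp06 import PARAM_NAMES

#: exclusion thresholds, in the order reasons are reported
RMP_MAX = -64.0  # mV
UPSTROKE_MAX = 10.0  # ms


@dataclass(frozen=True)
class CalibrationRange:
    cl: float  # ms
    apd90_lo: float  # ms
    apd90_hi: float  # ms

    def __post_init__(self):
        if not self.apd90_lo < self.apd90_hi:
            raise InvalidParameterError("calibration range requires lo < hi")

    def contains(self, apd90: float) -> bool:
        return self.apd90_lo <= apd90 <= self.apd90_hi


#: the two normative monophasic-APD calibration windows
DEFAULT_RANGES = (
    CalibrationRange(430.0, 170.0, 240.0),
    CalibrationRange(600.0, 195.0, 290.0),
)


@dataclass
class ModelRecord:
    """Audit-trail entry for one sampled parameter set."""

    params: ParameterSet
    accepted: bool
    reason: str | None  # None when accepted; first failed criterion otherwise
    biomarkers: dict = field(default_factory=dict)  # per-CL APBiomarkers
    traces: dict = field(default_factory=dict)  # per-CL APTrace (optional)
    final_states: dict = field(default_factory=dict)  # per-CL steady state


@dataclass
class Population:
    records: list
    seed: int
    n_samples: int
    ranges: tuple = DEFAULT_RANGES

    @property
    def accepted(self) -> list:
        return [r for r in self.records if r.accepted]

    @property
    def acceptance_fraction(self) -> float:
        return len(self.accepted) / len(self.records)

    def summary(self) -> dict:
        """Mean/SD of the single-cell biomarkers at CL 600 over accepted models."""
        cl = 600.0
        acc = self.accepted
        out = {"n_samples": self.n_samples, "n_accepted": len(acc),
               "acceptance_fraction": self.acceptance_fraction}
        for name in ("apd90", "apa", "rmp", "upstroke_time"):
            vals = np.array([getattr(r.biomarkers[cl], name) for r in acc])
            out[f"{name}_mean"] = float(vals.mean()) if acc else np.nan
            out[f"{name}_sd"] = float(vals.std(ddof=1)) if len(acc) > 1 else np.nan
        return out

    def write_index(self, path) -> None:
        """Flat CSV audit index (one row per sampled model)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["id", *PARAM_NAMES, "apd90_430", "apd90_600", "apa_600",
                 "rmp_600", "upstroke_600", "accepted", "reason"]
            )
            for r in self.records:
                b430 = r.biomarkers.get(430.0)
                b600 = r.biomarkers.get(600.0)
                w.writerow([
                    r.params.id,
                    *[f"{s:.6f}" for s in r.params.scales],
                    f"{b430.apd90:.3f}" if b430 else "",
                    f"{b600.apd90:.3f}" if b600 else "",
                    f"{b600.apa:.3f}" if b600 else "",
                    f"{b600.rmp:.3f}" if b600 else "",
                    f"{b600.upstroke_time:.3f}" if b600 else "",
                    int(r.accepted),
                    r.reason or "",
                ])


def lhs_points(n: int, dims: int, seed: int = 0) -> np.ndarray:
    """Latin Hypercube design of ``n`` points in [0, 2]^dims.

    Each one-dimensional marginal is stratified: exactly one sample falls
    in each interval [2k/n, 2(k+1)/n).
    """
    if n < 1:
        raise InvalidParameterError("need at least one sample")
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    return 2.0 * sampler.random(n)


def sample_lhs(n: int, dims: int = len(PARAM_NAMES), seed: int = 0) -> list:
    """Latin Hypercube Sample of ``n`` conductance-multiplier sets."""
    if dims != len(PARAM_NAMES):
        raise InvalidParameterError(
            f"parameter sets have {len(PARAM_NAMES)} dimensions"
        )
    pts = lhs_points(n, dims, seed)
    return [ParameterSet(scales=row, id=f"m{i:05d}") for i, row in enumerate(pts)]


def exclude(trace: APTrace, convention: str = "repol90"):
    """Apply the single-cell exclusion criteria to one saved beat.

    Returns ``(accepted, reason, biomarkers)``; the reason is the first
    failed criterion in the order APA, RMP, upstroke.
    """
    b = bm.ap_biomarkers(trace, convention=convention)
    if b.apa < 0.0:
        return False, "APA", b
    if b.rmp > RMP_MAX:
        return False, "RMP", b
    if b.upstroke_time > UPSTROKE_MAX:
        return False, "upstroke", b
    return True, None, b


def calibrate(apd90_by_cl: dict, ranges=DEFAULT_RANGES) -> bool:
    """Accept iff APD90 lies inside the closed window at every cycle length."""
    for rng in ranges:
        if rng.cl not in apd90_by_cl:
            raise InvalidParameterError(f"missing APD90 at CL {rng.cl}")
        apd = apd90_by_cl[rng.cl]
        if not np.isfinite(apd) or not rng.contains(apd):
            return False
    return True


def evaluate_model(
    params: ParameterSet,
    ranges=DEFAULT_RANGES,
    n_beats: int = 200,
    convention: str = "repol90",
    keep_traces: bool = False,
    spec: IschemiaSpec | None = None,
    **pace_kwargs,
) -> ModelRecord:
    """Pace one parameter set at every calibration CL and classify it.

    The slower cycle length is run first; exclusion criteria are applied
    there, and remaining cycle lengths are only simulated for survivors
    (acceptance is unchanged — a model rejected at one CL is rejected).
    """
    spec = spec or IschemiaSpec.control()
    cls_sorted = sorted((r.cl for r in ranges), reverse=True)
    rec = ModelRecord(params=params, accepted=False, reason=None)
    apd_by_cl = {}
    for i, cl in enumerate(cls_sorted):
        protocol = PacingProtocol(cl=cl, n_beats=n_beats)
        try:
            trace = pace_cell(params, spec, protocol, **pace_kwargs)
        except NumericalError:
            rec.reason = "numerical"
            return rec
        if keep_traces:
            rec.traces[cl] = trace
        rec.final_states[cl] = trace.final_state
        ok, reason, b = exclude(trace, convention=convention)
        rec.biomarkers[cl] = b
        if not ok:
            rec.reason = reason
            return rec
        apd_by_cl[cl] = b.apd90
        # early calibration check: no need to pace the other CL if this
        # one is already out of its window
        rng = next(r for r in ranges if r.cl == cl)
        if not np.isfinite(b.apd90) or not rng.contains(b.apd90):
            rec.reason = "calibration"
            return rec
    rec.accepted = calibrate(apd_by_cl, ranges)
    if not rec.accepted:
        rec.reason = "calibration"
    return rec


def build_control_epom(
    n_samples: int,
    seed: int,
    ranges=DEFAULT_RANGES,
    n_beats: int = 200,
    convention: str = "repol90",
    keep_traces: bool = False,
    progress: bool = False,
    **pace_kwargs,
) -> Population:
    """Full control-ePoM pipeline: LHS -> pace at both CLs -> exclude ->
    calibrate, with one audit record per sample."""
    params_list = sample_lhs(n_samples, seed=seed)
    records = []
    it = enumerate(params_list)
    if progress:
        from tqdm import tqdm

        it = tqdm(list(it), desc="ePoM")
    for _, params in it:
        records.append(
            evaluate_model(params, ranges, n_beats, convention,
                           keep_traces, **pace_kwargs)
        )
    return Population(records=records, seed=seed, n_samples=n_samples, ranges=tuple(ranges))
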