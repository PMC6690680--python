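"""Biomarker extraction: AP geometry, CV arithmetic, delineation, ratios."""

import numpy as np
import pytest

from epom.biomarkers import (
    BlockError,
    DelineationError,
    PECGBiomarkers,
    PropagationError,
    activation_time,
    ap_biomarkers,
    conduction_velocity,
    delineate_pecg,
    ratio_of_change,
)
from epom.cell_model import APTrace
from epom.pecg import PECGTrace


def trapezoid_ap(dt=0.1):
    """Rest -85, instant rise to +35 at t = 5, linear fall over [205, 245]."""
    t = np.arange(0.0, 400.0 + dt / 2, dt)
    v = np.full_like(t, -85.0)
    v[(t >= 5.0) & (t < 205.0)] = 35.0
    fall = (t >= 205.0) & (t <= 245.0)
    v[fall] = 35.0 - (t[fall] - 205.0) * (120.0 / 40.0)
    return APTrace(t=t, v=v, cl=400.0)


def triangle(t, start, apex, end, height):
    y = np.zeros_like(t)
    up = (t >= start) & (t <= apex)
    dn = (t > apex) & (t <= end)
    y[up] = height * (t[up] - start) / (apex - start)
    y[dn] = height * (end - t[dn]) / (end - apex)
    return y


@pytest.fixture
def triangle_trace():
    """QRS: triangle over [10, 40] ms peaking 1.0 at 25; T: triangle over
    [200, 260] peaking 0.5 at 230; flat zero elsewhere."""
    t = np.arange(0.0, 400.0, 0.05)
    phi = triangle(t, 10.0, 25.0, 40.0, 1.0) + triangle(t, 200.0, 230.0, 260.0, 0.5)
    return PECGTrace(t=t, phi=phi)


class TestAPBiomarkers:
    def test_trapezoid_closed_form_repol90(self):
        tr = trapezoid_ap()
        b = ap_biomarkers(tr, convention="repol90")
        assert b.apa == pytest.approx(35.0)
        assert b.rmp == pytest.approx(-85.0)
        # threshold 35 - 0.9*120 = -73; crossing at 205 + 108/3 = 241;
        # activation at the instant rise (t = 5)
        assert b.apd90 == pytest.approx(241.0 - 5.0, abs=0.2)

    def test_trapezoid_closed_form_apa_fraction(self):
        b = ap_biomarkers(trapezoid_ap(), convention="apa_fraction")
        # threshold 0.1*35 = 3.5; crossing at 205 + 31.5/3 = 215.5
        assert b.apd90 == pytest.approx(215.5 - 5.0, abs=0.2)

    def test_flat_trace_has_negative_apa_and_no_apd(self):
        t = np.arange(0.0, 100.0, 0.1)
        b = ap_biomarkers(APTrace(t=t, v=np.full_like(t, -85.0), cl=100.0))
        assert b.apa == pytest.approx(-85.0)
        assert np.isnan(b.apd90)

    def test_baseline_inside_calibration_window(self, baseline_trace_600):
        b = ap_biomarkers(baseline_trace_600, convention="apa_fraction")
        assert 195.0 <= b.apd90 <= 290.0

    def test_unknown_convention(self, baseline_trace_600):
        with pytest.raises(ValueError):
            ap_biomarkers(baseline_trace_600, convention="apd50")


class FakeSolution:
    def __init__(self, t, v, positions):
        self.t, self.v, self.positions = t, v, positions


def _cv_solution(at1=10.0, at2=30.0):
    """Cable whose V crosses zero at prescribed activation times."""
    pos = np.linspace(0.0, 2.0, 101)
    t = np.arange(0.0, 60.0, 0.5)
    ats = np.interp(pos, [0.4, 1.6], [at1, at2])
    v = np.where(t[:, None] > ats[None, :], 20.0, -85.0)
    return FakeSolution(t, v, pos)


class TestConductionVelocity:
    def test_eq_arithmetic(self):
        cv = conduction_velocity(_cv_solution(10.0, 30.0))
        assert cv.cv == pytest.approx(1.2 / 20.0 * 1000.0, rel=0.05)

    def test_equal_activation_times_rejected(self):
        with pytest.raises(PropagationError):
            conduction_velocity(_cv_solution(10.0, 10.0))

    def test_block_detected(self):
        pos = np.linspace(0.0, 2.0, 101)
        t = np.arange(0.0, 60.0, 0.5)
        v = np.full((t.size, pos.size), -85.0)
        with pytest.raises(BlockError):
            conduction_velocity(FakeSolution(t, v, pos))

    def test_activation_time_interpolates(self):
        t = np.array([0.0, 1.0, 2.0])
        v = np.array([-10.0, -10.0, 10.0])
        assert activation_time(t, v) == pytest.approx(1.5)


class TestDelineation:
    def test_triangle_threshold_oracle(self, triangle_trace):
        """Hand geometry: 10% crossings on the triangle flanks."""
        d = delineate_pecg(triangle_trace, t_method="threshold")
        assert d.qrs_onset == pytest.approx(11.5, abs=0.1)
        assert d.qrs_end == pytest.approx(38.5, abs=0.1)
        assert d.t_onset == pytest.approx(203.0, abs=0.1)
        assert d.t_end == pytest.approx(257.0, abs=0.1)
        assert d.qrs_duration == pytest.approx(27.0, abs=0.2)
        assert d.qt_interval == pytest.approx(257.0 - 11.5, abs=0.2)
        assert d.st_deviation == pytest.approx(0.0, abs=1e-9)
        assert d.qrs_amplitude == pytest.approx(1.0)
        assert d.t_amplitude == pytest.approx(0.5)

    def test_triangle_tangent_oracle(self, triangle_trace):
        """The tangent of a triangle flank is the flank itself, so the
        bounds land exactly on the triangle feet."""
        d = delineate_pecg(triangle_trace, t_method="tangent")
        assert d.t_onset == pytest.approx(200.0, abs=0.2)
        assert d.t_end == pytest.approx(260.0, abs=0.2)
        assert d.qrs_onset == pytest.approx(11.5, abs=0.1)  # QRS stays 10%-rule

    def test_zero_trace_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(DelineationError):
            delineate_pecg(PECGTrace(t=t, phi=np.zeros_like(t)))

    def test_negative_t_wave_handled(self, triangle_trace):
        phi = triangle_trace.phi.copy()
        mask = triangle_trace.t >= 150.0
        phi[mask] = -phi[mask]
        d = delineate_pecg(PECGTrace(t=triangle_trace.t, phi=phi),
                           t_method="threshold")
        assert d.t_amplitude == pytest.approx(-0.5)
        assert d.t_onset == pytest.approx(203.0, abs=0.1)

    def test_amplitude_scaling_invariance(self, triangle_trace):
        a = delineate_pecg(triangle_trace)
        b = delineate_pecg(PECGTrace(t=triangle_trace.t,
                                     phi=7.0 * triangle_trace.phi))
        for name in ("qrs_duration", "qt_interval", "t_duration"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=0.1)
        assert b.qrs_amplitude == pytest.approx(7.0 * a.qrs_amplitude)
        assert b.t_amplitude == pytest.approx(7.0 * a.t_amplitude)
        assert b.st_deviation == pytest.approx(7.0 * a.st_deviation, abs=1e-9)

    @pytest.mark.parametrize("delta", [5.0, 17.5])
    def test_time_shift_equivariance(self, triangle_trace, delta):
        shifted = delineate_pecg(
            PECGTrace(t=triangle_trace.t + delta, phi=triangle_trace.phi),
            stim_time=delta,
        )
        ref = delineate_pecg(triangle_trace)
        assert shifted.qrs_onset == pytest.approx(ref.qrs_onset + delta, abs=0.1)
        assert shifted.t_end == pytest.approx(ref.t_end + delta, abs=0.1)
        assert shifted.qt_interval == pytest.approx(ref.qt_interval, abs=0.1)
        assert shifted.qrs_duration == pytest.approx(ref.qrs_duration, abs=0.1)


class TestRatioOfChange:
    def _marks(self, **over):
        base = dict(qrs_duration=22.0, qt_interval=264.0, st_deviation=-0.2,
                    t_duration=34.0, qrs_amplitude=18.0, t_amplitude=-4.2)
        base.update(over)
        return PECGBiomarkers(**base)

    def test_identity(self):
        c = self._marks()
        r = ratio_of_change(c, c)
        for name, val in r.items():
            if not name.startswith("_"):
                assert val == pytest.approx(1.0)

    def test_arithmetic(self):
        c = self._marks(qt_interval=4.0)
        i = self._marks(qt_interval=2.0)
        assert ratio_of_change(c, i)["qt_interval"] == pytest.approx(0.5)

    def test_degenerate_control_substitutes_difference(self):
        c = self._marks(st_deviation=0.0)
        i = self._marks(st_deviation=-0.8)
        r = ratio_of_change(c, i)
        assert r["st_deviation"] == pytest.approx(-0.8)
        assert "st_deviation" in r["_substituted"]
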