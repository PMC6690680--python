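"""Single-cell model: ATP-sensitive current, ischemia overlay, pacing."""

import math

import numpy as np
import pytest

from epom import _tp06
from epom.biomarkers import ap_biomarkers
from epom.cell_model import (
    IschemiaSpec,
    InvalidParameterError,
    PacingProtocol,
    ParameterSet,
    cell_rhs,
    currents,
    ikatp_current,
    initial_state,
    nernst_k,
    pace_cell,
)


class TestIkatp:
    def test_zero_driving_force(self):
        spec = IschemiaSpec.severe()
        assert ikatp_current(spec, -70.0, -70.0) == 0.0

    def test_zero_scaling(self):
        spec = IschemiaSpec.control()  # f_katp = 0
        assert ikatp_current(spec, -50.0, -80.0) == 0.0

    def test_closed_form_severe(self):
        # independent transcription of the current law with plain floats:
        # f * G * (Ko/Ko_n)^0.24 * (V - EK), EK by Nernst at 310 K
        ek = (8314.472 * 310.0 / 96485.3415) * math.log(9.0 / 138.0)
        expected = 0.2 * 0.064 * (9.0 / 5.4) ** 0.24 * (-50.0 - ek)
        spec = IschemiaSpec.severe()
        got = ikatp_current(spec, -50.0, nernst_k(9.0, 138.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_control_potassium_factor_is_unity(self):
        spec = IschemiaSpec(f_katp=0.3, f_inhib=1.0, ko=5.4, label="control")
        v, ek = -40.0, -85.0
        assert ikatp_current(spec, v, ek) == pytest.approx(
            0.3 * _tp06.G_KATP * (v - ek), rel=1e-14
        )

    def test_invalid_ko(self):
        with pytest.raises(InvalidParameterError):
            IschemiaSpec(f_katp=0.1, f_inhib=1.0, ko=-1.0)


class TestPresets:
    def test_table_values(self):
        m, s = IschemiaSpec.mild(), IschemiaSpec.severe()
        assert (m.f_katp, m.f_inhib, m.ko) == (0.1, 0.875, 6.25)
        assert (s.f_katp, s.f_inhib, s.ko) == (0.2, 0.75, 9.0)
        c = IschemiaSpec.control()
        assert (c.f_katp, c.f_inhib, c.ko) == (0.0, 1.0, 5.4)

    def test_unknown_preset(self):
        with pytest.raises(InvalidParameterError):
            IschemiaSpec.preset("extreme")


class TestParameterSet:
    def test_range_validation(self):
        with pytest.raises(InvalidParameterError):
            ParameterSet(scales=np.full(12, 2.5))
        with pytest.raises(InvalidParameterError):
            ParameterSet(scales=np.full(5, 1.0))

    def test_roundtrip(self):
        p = ParameterSet(scales=np.linspace(0.1, 1.9, 12), id="x")
        q = ParameterSet.from_dict(p.to_dict())
        np.testing.assert_allclose(p.scales, q.scales)
        assert q.id == "x"


class TestRhs:
    def test_finhib_scales_ina_and_ical_linearly(self):
        y = initial_state()
        y[0] = -20.0  # depolarized so the currents are nonzero
        y[6:9] = 0.5
        y[14:17] = 0.5
        scales = np.ones(12)
        c1 = currents(y, scales, f_inhib=1.0)
        c2 = currents(y, scales, f_inhib=0.75)
        assert c2["i_na"] / c1["i_na"] == pytest.approx(0.75, rel=1e-12)
        assert c2["i_cal"] / c1["i_cal"] == pytest.approx(0.75, rel=1e-12)
        # other currents untouched
        assert c2["i_kr"] == pytest.approx(c1["i_kr"], rel=1e-14)

    @pytest.mark.parametrize("idx,key", [(0, "i_na"), (2, "i_kr"), (4, "i_k1"),
                                         (10, "i_nak"), (11, "i_naca")])
    def test_conductance_scaling_linearity(self, idx, key):
        y = initial_state()
        y[0] = -30.0
        y[6:17] = 0.4
        base = np.ones(12)
        doubled = base.copy()
        doubled[idx] = 2.0
        c1 = currents(y, base)
        c2 = currents(y, doubled)
        assert c2[key] == pytest.approx(2.0 * c1[key], rel=1e-12)

    def test_resting_derivative_small_after_relaxation(self, baseline):
        # relax unpaced for 2 s; the control model sits at a stable rest
        protocol = PacingProtocol(cl=1000.0, n_beats=2, stim_amplitude=0.0)
        tr = pace_cell(baseline, IschemiaSpec.control(), protocol)
        dy = cell_rhs(0.0, tr.final_state, baseline, IschemiaSpec.control())
        assert abs(dy[0]) < 0.01  # mV/ms

    def test_hyperkalemia_raises_resting_potential(self, baseline):
        protocol = PacingProtocol(cl=1000.0, n_beats=3, stim_amplitude=0.0)
        rest_c = pace_cell(baseline, IschemiaSpec.control(), protocol).v[-1]
        rest_s = pace_cell(baseline, IschemiaSpec.severe(), protocol).v[-1]
        assert rest_s > rest_c + 5.0

    def test_ek_follows_nernst(self):
        y = initial_state()
        c = currents(y, np.ones(12), ko=9.0)
        assert c["ek"] == pytest.approx(_tp06.RTONF * np.log(9.0 / y[2]), rel=1e-12)


class TestPacing:
    def test_determinism(self, baseline):
        protocol = PacingProtocol(cl=600.0, n_beats=5)
        a = pace_cell(baseline, IschemiaSpec.control(), protocol)
        b = pace_cell(baseline, IschemiaSpec.control(), protocol)
        assert np.array_equal(a.v, b.v)

    def test_zero_stimulus_no_upstroke(self, baseline):
        protocol = PacingProtocol(cl=600.0, n_beats=3, stim_amplitude=0.0)
        tr = pace_cell(baseline, IschemiaSpec.control(), protocol)
        assert tr.v.max() < 0.0  # APA below zero: no excitation

    def test_protocol_validation(self):
        with pytest.raises(InvalidParameterError):
            PacingProtocol(cl=0.5, stim_duration=1.0)
        with pytest.raises(InvalidParameterError):
            PacingProtocol(n_beats=0)

    def test_ischemia_monotonicity(self, baseline):
        protocol = PacingProtocol(cl=600.0, n_beats=200)
        marks = {}
        for label in ("control", "mild", "severe"):
            tr = pace_cell(baseline, IschemiaSpec.preset(label), protocol)
            marks[label] = ap_biomarkers(tr)
        assert marks["control"].apd90 > marks["mild"].apd90 > marks["severe"].apd90
        assert marks["control"].rmp < marks["mild"].rmp < marks["severe"].rmp
        assert marks["control"].apa > marks["severe"].apa

    def test_steady_pacing_is_convergent(self, baseline, baseline_trace_600):
        """After 200 pre-pacing beats the baseline cell shows no APD
        alternans: the beat-to-beat APD90 swing stays under 1 ms."""
        protocol = PacingProtocol(cl=600.0, n_beats=1)
        tr = pace_cell(baseline, IschemiaSpec.control(), protocol,
                       initial=baseline_trace_600.final_state,
                       check_alternans=True)
        assert tr.meta["non_convergent"] is False
        assert tr.meta["apd_beat_to_beat_ms"] < 1.0

    def test_fixed_step_matches_stiff_reference(self, baseline, baseline_trace_600):
        """The fast Rush-Larsen path agrees with LSODA at the reference
        tolerances, continuing from the same steady state."""
        protocol = PacingProtocol(cl=600.0, n_beats=1)
        start = baseline_trace_600.final_state
        rl = pace_cell(baseline, IschemiaSpec.control(), protocol, initial=start)
        ls = pace_cell(baseline, IschemiaSpec.control(), protocol,
                       solver="lsoda", initial=start)
        b_rl = ap_biomarkers(rl)
        b_ls = ap_biomarkers(ls)
        assert b_rl.apd90 == pytest.approx(b_ls.apd90, abs=1.0)
        assert b_rl.apa == pytest.approx(b_ls.apa, abs=1.0)
        assert b_rl.rmp == pytest.approx(b_ls.rmp, abs=0.5)
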