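"""Calibrated MAPK/ERK ODE model."""

import numpy as np
import pytest

from mapkinfo.model import (
    DEFAULT_PARAMETERS,
    ModelParameters,
    ProtocolSpec,
    R_MAX_NOMINAL,
    amplitude_response,
    integrated_response,
    measure_relaxation_time,
    oscillates,
    scan_feedback_strength,
    simulate,
)
from mapkinfo.model import _two_pulse_ratio


@pytest.fixture(scope="module")
def single_pulse_traj():
    proto = ProtocolSpec.from_sequence("1", T=60.0)
    return simulate(DEFAULT_PARAMETERS, proto, horizon=60.0, keep_state=True)


@pytest.fixture(scope="module")
def r_max(single_pulse_traj):
    return integrated_response(single_pulse_traj, 60.0, 1).R[0]


class TestSimulate:
    def test_zero_input_stays_at_baseline(self):
        proto = ProtocolSpec.from_sequence("00", T=60.0)
        traj = simulate(DEFAULT_PARAMETERS, proto)
        assert traj.ERK_pp.max() < 0.01 * DEFAULT_PARAMETERS["E_tot"]
        R = integrated_response(traj, 60.0, 2).R
        assert np.all(R < 0.01 * R_MAX_NOMINAL)

    def test_single_pulse_duration_about_half_hour(self, single_pulse_traj):
        E = single_pulse_traj.ERK_pp
        above = single_pulse_traj.t[E > 0.5 * E.max()]
        width = above[-1] - above[0]
        assert 15.0 < width < 35.0
        # most of the integrated response accrues within the first 30 min
        m = single_pulse_traj.t <= 30.0
        frac = np.trapezoid(E[m], single_pulse_traj.t[m]) / np.trapezoid(
            E, single_pulse_traj.t
        )
        assert frac > 0.8

    def test_deterministic_reproducibility(self):
        proto = ProtocolSpec.from_sequence("101", T=30.0)
        a = simulate(DEFAULT_PARAMETERS, proto)
        b = simulate(DEFAULT_PARAMETERS, proto)
        assert np.array_equal(a.ERK_pp, b.ERK_pp)

    def test_states_bounded_by_pools(self, single_pulse_traj):
        y = single_pulse_traj.state
        assert y is not None
        assert np.all(y >= -1e-9)
        assert np.all(y <= 1.0 + 1e-9)

    def test_constant_intermediate_egf_oscillates(self):
        assert oscillates(DEFAULT_PARAMETERS, 5.0)

    def test_high_egf_does_not_oscillate(self):
        assert not oscillates(DEFAULT_PARAMETERS, 100.0)


class TestIntegratedResponse:
    def test_r_max_calibration(self, r_max):
        assert r_max == pytest.approx(R_MAX_NOMINAL, rel=0.05)

    def test_two_pulses_T60_second_response_partial(self):
        proto = ProtocolSpec.from_sequence("11", T=60.0)
        traj = simulate(DEFAULT_PARAMETERS, proto)
        R = integrated_response(traj, 60.0, 2).R
        # above the relaxation time but not fully recovered
        assert 0.5 < R[1] / R[0] < 0.9

    def test_zero_trajectory_gives_zero_response(self):
        from mapkinfo.model import Trajectory

        traj = Trajectory(t=np.linspace(0, 120, 500), ERK_pp=np.zeros(500))
        assert np.all(integrated_response(traj, 60.0, 2).R == 0.0)

    def test_short_trajectory_rejected(self, single_pulse_traj):
        with pytest.raises(ValueError):
            integrated_response(single_pulse_traj, 60.0, 4)


class TestRelaxationTime:
    def test_tau_matches_calibration(self):
        tau = measure_relaxation_time(DEFAULT_PARAMETERS)
        assert tau == pytest.approx(51.5, abs=1.0)

    def test_ratio_negligible_below_and_partial_above(self):
        assert _two_pulse_ratio(DEFAULT_PARAMETERS, 45.0) < 0.25
        assert 0.5 < _two_pulse_ratio(DEFAULT_PARAMETERS, 60.0) < 0.9

    def test_ratio_nondecreasing_on_scan(self):
        ratios = [_two_pulse_ratio(DEFAULT_PARAMETERS, T) for T in (40, 50, 60, 70, 80)]
        assert all(b >= a - 0.02 for a, b in zip(ratios, ratios[1:]))

    def test_miscalibration_raises(self):
        # no refractoriness at all: ratio never crosses 0.5 inside the bracket
        broken = DEFAULT_PARAMETERS.with_values({"nf1_scale": 0.05})
        with pytest.raises(RuntimeError):
            measure_relaxation_time(broken, bracket=(30.0, 40.0))


class TestAmplitudeResponse:
    def test_digital_dose_response(self, r_max):
        assert amplitude_response(DEFAULT_PARAMETERS, 3.0) < 0.1 * r_max
        for dose in (10.0, 30.0, 100.0):
            assert amplitude_response(DEFAULT_PARAMETERS, dose) > 0.7 * r_max

    def test_zero_dose(self):
        assert amplitude_response(DEFAULT_PARAMETERS, 0.0) == 0.0

    def test_four_pulse_mixed_doses(self, r_max):
        # 3, 100, 10, 30 pg/ml at T=60: no response to the first pulse only
        proto = ProtocolSpec(T=60.0, amplitudes=(3.0, 100.0, 10.0, 30.0))
        traj = simulate(DEFAULT_PARAMETERS, proto)
        R = integrated_response(traj, 60.0, 4).R
        assert R[0] < 0.1 * r_max
        assert all(r > 0.4 * r_max for r in R[1:])


class TestFeedbackScan:
    def test_scale_one_consistent_and_oscillation_vanishes_when_weak(self):
        df = scan_feedback_strength(
            DEFAULT_PARAMETERS, scale_grid=(0.15, 1.0), dose_grid=(4.0, 5.0, 10.0)
        )
        nominal = df[df.scale == 1.0].iloc[0]
        assert nominal.oscillates
        assert nominal.tau_min == pytest.approx(
            measure_relaxation_time(DEFAULT_PARAMETERS, leakage_corrected=True), abs=0.5
        )
        weak = df[df.scale == 0.15].iloc[0]
        assert not weak.oscillates

    def test_rejects_out_of_range_scale(self):
        with pytest.raises(ValueError):
            scan_feedback_strength(DEFAULT_PARAMETERS, scale_grid=(1.5,))


class TestParameters:
    def test_roundtrip_through_table(self):
        df = DEFAULT_PARAMETERS.to_frame()
        back = ModelParameters.from_frame(df)
        assert back.values == DEFAULT_PARAMETERS.values
        assert back.cell_variable == DEFAULT_PARAMETERS.cell_variable

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            DEFAULT_PARAMETERS.with_values({"bogus": 1.0})

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ProtocolSpec(T=4.0, amplitudes=(100.0,))  # pulse longer than slot
        with pytest.raises(ValueError):
            ProtocolSpec(T=60.0, amplitudes=())
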