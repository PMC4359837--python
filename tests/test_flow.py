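"""Flow solver: boundary-condition arithmetic and coarse-mesh physics."""

import numpy as np
import pytest

from coroflow import (BloodProperties, FlowBC, WaveformSpec, compute_wss,
                      mass_flow_rate, outlet_mean_velocity, reynolds,
                      solve_steady, solve_transient, synth_waveform)
from coroflow.flow import outlet_pressure_waveform
from coroflow.waveforms import cycle_mean


class TestBoundaryArithmetic:
    @pytest.mark.parametrize("v,ratio,expected", [
        (0.30, 0.76, 0.228),   # Doppler correction scenario
        (0.30, 1.0, 0.30),     # measured-as-mean
        (0.30, 0.5, 0.15),     # generalized Poiseuille
    ])
    def test_outlet_mean_velocity(self, v, ratio, expected):
        assert outlet_mean_velocity(v, ratio) == pytest.approx(expected)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            outlet_mean_velocity(0.3, 0.0)
        with pytest.raises(ValueError):
            outlet_mean_velocity(-0.1, 0.76)

    def test_mass_flow_rate(self, blood):
        area = np.pi * 1.5e-3**2
        assert mass_flow_rate(blood, 0.2, area) == pytest.approx(
            1.4985e-3, rel=1e-3)
        assert mass_flow_rate(blood, 0.0, area) == 0.0
        assert mass_flow_rate(blood, 0.2, 2 * area) == pytest.approx(
            2 * mass_flow_rate(blood, 0.2, area))

    def test_reynolds(self, blood):
        assert reynolds(blood, 0.2, 0.003) == pytest.approx(181.7, rel=1e-3)
        assert reynolds(blood, 0.0, 0.003) == 0.0

    def test_default_conditions_sit_in_the_laminar_study_band(self, blood):
        # hyperemic distal velocities of the cohort gave Re 126-883
        v = WaveformSpec(kind="velocity", mean=0.2, pulse_amplitude=0.2)
        re_mean = reynolds(blood, v.mean, 0.003)
        assert 126 <= re_mean <= 883


class TestSteadySolve:
    def test_zero_flow_is_hydrostatic(self, coarse_straight_mesh, blood):
        bc = FlowBC(inlet_pressure=100.0, outlet_velocity_measured=0.0)
        sol = solve_steady(coarse_straight_mesh, blood, bc)
        assert np.abs(sol.v).max() < 1e-9
        assert sol.p == pytest.approx(100.0 * 133.322, rel=1e-6)

    def test_global_mass_conservation(self, coarse_straight_solution):
        sol = coarse_straight_solution
        assert abs(sol.flow_in + sol.flow_out) / abs(sol.flow_out) < 1e-6

    def test_no_slip_on_wall(self, coarse_straight_solution):
        wall = coarse_straight_solution.mesh.patches["wall_interface"].nodes
        assert np.abs(coarse_straight_solution.v[wall]).max() < 1e-12

    def test_pressure_drops_downstream(self, coarse_straight_solution):
        sol = coarse_straight_solution
        assert sol.inlet_pressure_mmhg > sol.outlet_pressure_mmhg
        assert sol.inlet_pressure_mmhg == pytest.approx(100.0, rel=5e-3)

    def test_stenosis_increases_pressure_drop(
            self, coarse_straight_solution, coarse_stenosed_mesh, blood,
            steady_bc):
        sten = solve_steady(coarse_stenosed_mesh, blood, steady_bc)
        dp_straight = (coarse_straight_solution.inlet_pressure_mmhg
                       - coarse_straight_solution.outlet_pressure_mmhg)
        dp_sten = sten.inlet_pressure_mmhg - sten.outlet_pressure_mmhg
        assert dp_sten > dp_straight

    def test_wss_peaks_at_the_throat(self, coarse_stenosed_mesh, blood,
                                     steady_bc):
        sol = solve_steady(coarse_stenosed_mesh, blood, steady_bc)
        wss_throat = compute_wss(sol, 5.0, blood)
        wss_inlet = compute_wss(sol, 1.0, blood)
        assert wss_throat > wss_inlet

    def test_zero_flow_wss_is_zero(self, coarse_straight_mesh, blood):
        bc = FlowBC(inlet_pressure=100.0, outlet_velocity_measured=0.0)
        sol = solve_steady(coarse_straight_mesh, blood, bc)
        assert compute_wss(sol, 5.0, blood) == pytest.approx(0.0, abs=1e-8)

    def test_wss_section_outside_vessel_rejected(
            self, coarse_straight_solution, blood):
        with pytest.raises(ValueError, match="outside"):
            compute_wss(coarse_straight_solution, 25.0, blood)

    def test_turbulent_regime_rejected(self, coarse_straight_mesh, blood):
        bc = FlowBC(inlet_pressure=100.0, outlet_velocity_measured=2.5)
        with pytest.raises(ValueError, match="Reynolds"):
            solve_steady(coarse_straight_mesh, blood, bc)

    def test_waveform_bc_rejected_in_steady_solver(self, coarse_straight_mesh,
                                                   blood):
        pw = synth_waveform(WaveformSpec())
        with pytest.raises(ValueError, match="scalar"):
            solve_steady(coarse_straight_mesh, blood,
                         FlowBC(pw, 0.2))


class TestTransientSolve:
    def test_constant_waveforms_match_steady(self, coarse_straight_mesh,
                                             blood, steady_bc):
        pw = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=0.0))
        vw = synth_waveform(WaveformSpec(kind="velocity", mean=0.2,
                                         pulse_amplitude=0.0))
        steady = solve_steady(coarse_straight_mesh, blood, steady_bc)
        sols = solve_transient(coarse_straight_mesh, blood, FlowBC(pw, vw),
                               dt=0.1)
        for s in sols:
            assert s.outlet_pressure_mmhg == pytest.approx(
                steady.outlet_pressure_mmhg, rel=5e-3)

    def test_outlet_pressure_waveform_structure(self, coarse_straight_mesh,
                                                blood):
        pw = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=20.0))
        vw = synth_waveform(WaveformSpec(kind="velocity", mean=0.2,
                                         pulse_amplitude=0.1))
        sols = solve_transient(coarse_straight_mesh, blood, FlowBC(pw, vw),
                               dt=0.05)
        out = outlet_pressure_waveform(sols)
        assert len(out.values) == len(pw.values)
        # distal pressure tracks the inlet waveform to leading order
        assert cycle_mean(out) == pytest.approx(100.0, rel=0.02)
        assert np.ptp(out.values) > 5.0

    def test_mismatched_periods_rejected(self, coarse_straight_mesh, blood):
        pw = synth_waveform(WaveformSpec(period=0.8))
        vw = synth_waveform(WaveformSpec(kind="velocity", mean=0.2,
                                         period=1.0))
        with pytest.raises(ValueError, match="period"):
            solve_transient(coarse_straight_mesh, blood, FlowBC(pw, vw))
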