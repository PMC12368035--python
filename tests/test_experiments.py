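"""Composed in-silico experiments: steady shift, pulse decay, rate scans."""

import numpy as np
import pytest

import caclear as cc


class TestSteadyExperiment:
    def test_no_pump_reduces_to_uniform_curve(self, pipette_geometry, truth,
                                              v_grid):
        curve = cc.run_steady_experiment(
            pipette_geometry, cc.PumpParams(cycle_rate=0.0), truth.bk_steady,
            c_pip=10.0, v_grid=v_grid,
        )
        ref = cc.steady_activation_curve(truth.bk_steady, 10.0, v_grid)
        assert np.abs(curve.g_norm - ref).max() < 1e-9

    def test_fast_pumps_shift_activation_right(self, pipette_geometry, truth):
        """Raising the cycle rate shifts V_h to positive potentials,
        toward the resting-calcium calibration curve."""
        vh = {}
        for rate in (50.0, 5000.0):
            vh[rate] = cc.run_steady_experiment(
                pipette_geometry, cc.PumpParams(cycle_rate=rate),
                truth.bk_steady, n_r=40, n_x=96,
            ).fitted_vh
        assert vh[5000.0] > vh[50.0]
        cal_vh = cc.fit_boltzmann(
            np.arange(-80.0, 201.0, 10.0),
            cc.steady_activation_curve(truth.bk_steady, 0.1,
                                       np.arange(-80.0, 201.0, 10.0)),
        )[0]
        assert abs(vh[5000.0] - cal_vh) < 10.0


class TestPulseExperiment:
    def test_buffer_limited_decay_is_deactivation_limited(self,
                                                          pulse_buffered,
                                                          truth):
        """10 mM EGTA clears the pulse in < 1 ms; the K⁺-current decay is
        then set by channel deactivation."""
        tau = pulse_buffered.trace.tau_decay
        tau_deact = cc.deactivation_tau(truth.bk_kinetic, 70.0, 0.1)
        assert tau == pytest.approx(tau_deact, rel=0.15)
        assert 5.9 <= tau <= 10.9

    def test_low_buffer_without_pumps_is_persistent(self, pulse_pumped):
        res = pulse_pumped(0.0)
        assert res.trace.tau_decay is None  # persistent: no decay fit
        assert res.trace.values[-1] > 0.5 * res.trace.values.max()

    def test_tau_strictly_decreasing_in_cycle_rate(self, pulse_pumped):
        taus = [pulse_pumped(r).trace.tau_decay
                for r in (5000.0, 10000.0, 20000.0)]
        assert taus[0] > taus[1] > taus[2]

    def test_pump_density_and_rate_enter_as_product(self, geometry, truth,
                                                    protocol):
        """Doubling density at half the rate gives the identical flux,
        hence the identical trace (flux enters only as φ·ρ)."""
        a = cc.run_pulse_experiment(
            geometry, cc.PumpParams(cycle_rate=20000.0, density=50.0),
            cc.BufferParams(b_total=0.0), protocol, truth.bk_kinetic,
        )
        b = cc.run_pulse_experiment(
            geometry, cc.PumpParams(cycle_rate=10000.0, density=100.0),
            cc.BufferParams(b_total=0.0), protocol, truth.bk_kinetic,
        )
        assert a.trace.tau_decay == pytest.approx(b.trace.tau_decay,
                                                  rel=1e-6)

    def test_multi_pulse_prolongs_decay(self, geometry, truth,
                                        pulse_buffered, pulse_pumped):
        """Five pulses at 500-ish Hz: τ_decay is at least the single-pulse
        value for both the buffer and the pump condition."""
        prot5 = cc.InfluxProtocol(n_pulses=5, record_duration=112.0)
        eg5 = cc.run_pulse_experiment(
            geometry, cc.PumpParams(cycle_rate=0.0),
            cc.BufferParams(b_total=10000.0), prot5, truth.bk_kinetic,
        )
        pm5 = cc.run_pulse_experiment(
            geometry, cc.PumpParams(cycle_rate=20000.0),
            cc.BufferParams(b_total=0.0), prot5, truth.bk_kinetic,
        )
        assert eg5.trace.tau_decay >= pulse_buffered.trace.tau_decay - 0.05
        assert pm5.trace.tau_decay >= pulse_pumped(20000.0).trace.tau_decay

    def test_volume_readout_is_config_alternative(self, geometry, truth,
                                                  protocol):
        res = cc.run_pulse_experiment(
            geometry, cc.PumpParams(cycle_rate=20000.0),
            cc.BufferParams(b_total=0.0), protocol, truth.bk_kinetic,
            readout="volume",
        )
        assert res.trace.tau_decay is not None
        with pytest.raises(ValueError):
            cc.run_pulse_experiment(
                geometry, cc.PumpParams(), cc.BufferParams(), protocol,
                truth.bk_kinetic, readout="bogus",
            )


class TestRateScan:
    def test_steady_scan_monotone_with_overlay(self, pipette_geometry, truth):
        scan = cc.scan_pump_rates(
            (50.0, 500.0, 5000.0), "steady", pipette_geometry,
            cc.PumpParams(), bk_steady=truth.bk_steady,
        )
        assert np.all(np.diff(scan.values) > 0)
        # slow pumps leave the curve far from the resting calibration
        assert abs(scan.values[0] - scan.reference) > scan.tolerance
        assert scan.minimal_sufficient_rate is not None

    def test_pulse_scan_ordering(self, pulse_pumped):
        taus = {r: pulse_pumped(r).trace.tau_decay
                for r in (5000.0, 20000.0)}
        assert taus[20000.0] < taus[5000.0]

    def test_scan_input_validation(self, pipette_geometry, truth):
        with pytest.raises(ValueError):
            cc.scan_pump_rates((50.0,), "steady", pipette_geometry,
                               cc.PumpParams(), bk_steady=truth.bk_steady)
        with pytest.raises(ValueError):
            cc.scan_pump_rates((50.0, 500.0), "bogus", pipette_geometry,
                               cc.PumpParams(), bk_steady=truth.bk_steady)
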