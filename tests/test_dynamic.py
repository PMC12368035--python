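"""Dynamic reaction-diffusion solver: rest state, conservation, buffer
kinetics, the well-mixed fast-diffusion limit, and mesh convergence."""

import numpy as np
import pytest

import caclear as cc


@pytest.fixture(scope="module")
def short_protocol():
    return cc.InfluxProtocol(record_duration=10.0)


def test_rest_state_is_stationary(geometry, short_protocol):
    """No influx, no pump: the equilibrated initial state stays put."""
    pump = cc.PumpParams(cycle_rate=0.0)
    buf = cc.BufferParams(b_total=100.0)
    prot = cc.InfluxProtocol(ions_per_pulse=1e-12, record_duration=5.0)
    s = cc.solve_dynamic(geometry, pump, buf, prot)
    assert np.allclose(s.free_ca, pump.resting_c0, rtol=1e-6)
    b0 = buf.b_total * buf.free_fraction_at(pump.resting_c0)
    assert np.allclose(s.free_buffer, b0, rtol=1e-6)


def test_closed_cell_conserves_total_calcium(geometry, short_protocol):
    """After the pulse ends (no pump, no leak) free+bound Ca is constant."""
    pump = cc.PumpParams(cycle_rate=0.0)
    buf = cc.BufferParams(b_total=100.0)
    s = cc.solve_dynamic(geometry, pump, buf, short_protocol)
    ions = s.total_calcium_ions()
    post = ions[s.times >= 0.81]
    assert (post.max() - post.min()) / post.mean() < 1e-6
    # and the influx itself delivered exactly the prescribed ions
    pre = ions[s.times < 0.0]
    assert ions[-1] - pre[0] == pytest.approx(1.2e6, rel=1e-6)


def test_end_of_pulse_concentration_low_buffer(geometry, short_protocol):
    """0.1 mM EGTA barely dents the 13.6 µM budget within 0.8 ms; the
    volume-averaged level lands around 10 µM as reported."""
    s = cc.solve_dynamic(geometry, cc.PumpParams(cycle_rate=0.0),
                         cc.BufferParams(b_total=100.0), short_protocol)
    i = int(np.argmin(np.abs(s.times - 0.8)))
    assert 6.0 <= s.c_volume[i] <= 14.0
    assert s.c_volume[i] == pytest.approx(12.9, abs=0.3)


def test_high_buffer_absorbs_pulse_within_a_millisecond(geometry,
                                                        short_protocol):
    """10 mM EGTA: free Ca falls below 1 µM within 1 ms of pulse end."""
    s = cc.solve_dynamic(geometry, cc.PumpParams(cycle_rate=0.0),
                         cc.BufferParams(b_total=10000.0), short_protocol)
    i = int(np.argmin(np.abs(s.times - 1.8)))
    assert s.c_volume[i] < 1.0
    assert s.c_membrane[i] < 1.0


def test_positivity_and_buffer_bounds(geometry, short_protocol):
    s = cc.solve_dynamic(geometry, cc.PumpParams(cycle_rate=20000.0),
                         cc.BufferParams(b_total=10000.0), short_protocol)
    assert s.free_ca.min() >= 0.0
    assert s.free_buffer.min() >= 0.0
    assert s.free_buffer.max() <= 10000.0 * (1 + 1e-9)


def test_fast_diffusion_limit_matches_wellmixed_ode(geometry):
    """With diffusivities ×100 the PDE volume average tracks the
    two-variable ODE oracle to better than 2% everywhere."""
    pump = cc.PumpParams(cycle_rate=20000.0)
    buf = cc.BufferParams(b_total=100.0, diff_coeff=11000.0)
    prot = cc.InfluxProtocol(record_duration=15.0)
    s = cc.solve_dynamic(geometry, pump, buf, prot, d_ca=22000.0)
    t, c_ode, _ = cc.wellmixed_reference(geometry, pump, buf, prot,
                                         times=s.times)
    scale = c_ode.max()
    assert np.max(np.abs(s.c_volume - c_ode)) / scale < 0.02


def test_wellmixed_reference_pump_slope_and_buffer_equilibrium(geometry):
    """ODE oracle spot checks: saturated pump drains 3.40 µM/ms; buffer
    equilibrium free fraction at rest is k_off/(k_off + k_on·c)."""
    pump = cc.PumpParams(cycle_rate=20000.0, density=50.0)
    area_flux = cc.pump_outflux_density(1e9, pump) * geometry.surface_area
    dc_dt = area_flux / (cc.IONS_PER_UM_UM3 * geometry.accessible_volume) / 1e3
    assert dc_dt == pytest.approx(3.40, abs=0.01)

    buf = cc.BufferParams(b_total=100.0, k_on=2.7, k_off=0.4)
    assert buf.free_fraction_at(0.1) == pytest.approx(0.597, abs=1e-3)

    # no influx and no pump: oracle trace is constant
    prot = cc.InfluxProtocol(ions_per_pulse=1e-12, record_duration=5.0)
    t, c, b = cc.wellmixed_reference(geometry, cc.PumpParams(cycle_rate=0.0),
                                     buf, prot)
    assert np.allclose(c, 0.1, rtol=1e-8)


def test_mesh_refinement_converges(geometry):
    """Halving the mesh spacing moves the τ-relevant summaries < 2%."""
    pump = cc.PumpParams(cycle_rate=20000.0)
    buf = cc.BufferParams(b_total=0.0)
    prot = cc.InfluxProtocol(record_duration=20.0)
    coarse = cc.solve_dynamic(geometry, pump, buf, prot, n_shells=48,
                              membrane_dr=0.008)
    fine = cc.solve_dynamic(geometry, pump, buf, prot, n_shells=96,
                            membrane_dr=0.004)

    def t_below(series, level=1.0):
        below = series.times[series.c_membrane < level]
        return below[below > 0.8][0]

    assert t_below(fine) == pytest.approx(t_below(coarse), rel=0.02)
    i_c = int(np.argmin(np.abs(coarse.times - 0.8)))
    i_f = int(np.argmin(np.abs(fine.times - 0.8)))
    assert fine.c_volume[i_f] == pytest.approx(coarse.c_volume[i_c], rel=0.02)


def test_summary_reproducible_from_fields(geometry, short_protocol):
    s = cc.solve_dynamic(geometry, cc.PumpParams(cycle_rate=0.0),
                         cc.BufferParams(b_total=100.0), short_protocol)
    i = s.times.size // 2
    f = s.field_at(i)
    assert f.volume_average == pytest.approx(s.c_volume[i], rel=1e-9)
    assert f.membrane_average == pytest.approx(s.c_membrane[i], rel=1e-9)
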