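"""Ten-state BK gating model: closed-form equilibrium, generator
consistency, detailed balance and master-equation propagation."""

import numpy as np
import pytest

import caclear as cc
from caclear.gating import N_STATES, equilibrium_occupancy


@pytest.fixture(scope="module")
def steady(truth):
    return truth.bk_steady


@pytest.fixture(scope="module")
def kinetic(truth):
    return truth.bk_kinetic


class TestBFactor:
    def test_zero_calcium(self, steady):
        assert cc.b_factor(0.0, steady) == 1.0

    def test_saturating_limit(self, steady):
        lim = np.prod(steady.ko) / np.prod(steady.kc)
        assert cc.b_factor(1e9, steady) == pytest.approx(lim, rel=1e-4)

    def test_toy_polynomials(self):
        """Direct polynomial arithmetic: kc=10 gives 1+0.1+…+1e-4 = 1.1111,
        ko=1 gives 1+1+1+1+1 = 5."""
        p = cc.BKSteadyParams(l0=10.0, gating_charge_q=1.0,
                              kc=(10.0,) * 4, ko=(1.0,) * 4)
        assert cc.b_factor(1.0, p) == pytest.approx(1.1111 / 5.0, abs=1e-4)

    def test_negative_rejected(self, steady):
        with pytest.raises(ValueError):
            cc.b_factor(-1.0, steady)


class TestPopenSteady:
    def test_half_activation_by_construction(self, steady):
        """At the voltage where B·L0·exp(−QFV/RT) = 1, P_open = 1/2."""
        c = 1.0
        const = cc.DEFAULT_CONSTANTS
        vh = np.log(cc.b_factor(c, steady) * steady.l0) / (
            steady.gating_charge_q * const.faraday_over_RT_per_mV
        )
        assert cc.popen_steady(vh, c, steady) == pytest.approx(0.5, rel=1e-9)

    def test_limits_and_simple_value(self, steady):
        assert cc.popen_steady(2000.0, 0.1, steady) == pytest.approx(1.0,
                                                                     abs=1e-6)
        p = cc.BKSteadyParams(l0=9.0, gating_charge_q=1.0,
                              kc=(1.0,) * 4, ko=(1.0,) * 4)
        assert cc.popen_steady(0.0, 0.0, p) == pytest.approx(0.1, rel=1e-12)

    def test_monotone_in_v_and_c(self, steady):
        v = np.linspace(-100, 250, 71)
        po = cc.popen_steady(v, 1.0, steady)
        assert np.all(np.diff(po) > 0)
        assert cc.popen_steady(100.0, 10.0, steady) > \
            cc.popen_steady(100.0, 0.1, steady)


class TestActivationCurve:
    def test_normalized_and_monotone(self, steady, v_grid):
        g = cc.steady_activation_curve(steady, 1.0, v_grid)
        assert g.max() == 1.0
        assert np.all(np.diff(g) >= 0)

    def test_calcium_left_shift(self, steady, v_grid):
        vh_low = cc.fit_boltzmann(v_grid,
                                  cc.steady_activation_curve(steady, 0.1,
                                                             v_grid))[0]
        vh_high = cc.fit_boltzmann(v_grid,
                                   cc.steady_activation_curve(steady, 10.0,
                                                              v_grid))[0]
        assert vh_high < vh_low


class TestGenerator:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_rows_sum_to_zero(self, kinetic, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            G = cc.build_generator(rng.uniform(-80, 200),
                                   rng.uniform(0, 50), kinetic)
            assert np.abs(G.sum(axis=1)).max() < 1e-9 * np.abs(G).max()

    def test_no_binding_without_calcium(self, kinetic):
        G = cc.build_generator(50.0, 0.0, kinetic)
        for i in range(4):
            assert G[i, i + 1] == 0.0
            assert G[5 + i, 5 + i + 1] == 0.0

    def test_equilibrium_reproduces_closed_form(self, kinetic):
        """Stationary distribution of the generator matches the
        equilibrium open probability at 100 random (V, c) points."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            v = rng.uniform(-80.0, 200.0)
            c = rng.uniform(0.0, 50.0)
            pi = cc.stationary_distribution(cc.build_generator(v, c, kinetic))
            assert pi[5:].sum() == pytest.approx(
                cc.popen_steady(v, c, kinetic.steady), abs=1e-6
            )

    def test_detailed_balance_cycles(self, kinetic):
        cycles = cc.detailed_balance_cycles(kinetic, v=37.0, c=2.2)
        assert np.abs(cycles - 1.0).max() < 1e-8

    def test_closed_form_equilibrium_occupancy(self, kinetic):
        occ = equilibrium_occupancy(70.0, 1.0, kinetic.steady).occupancy
        pi = cc.stationary_distribution(cc.build_generator(70.0, 1.0, kinetic))
        assert np.abs(occ - pi).max() < 1e-8


class TestPopenDynamic:
    def test_constant_inputs_converge_to_steady(self, kinetic):
        t = np.arange(0.0, 120.0, 0.05)
        c = np.full_like(t, 0.5)
        v = np.full_like(t, 70.0)
        init = equilibrium_occupancy(70.0, 50.0, kinetic.steady)
        po = cc.popen_dynamic(c, v, t, kinetic, init=init)
        assert po[-1] == pytest.approx(
            cc.popen_steady(70.0, 0.5, kinetic.steady), abs=1e-4
        )

    def test_steady_init_gives_flat_trace(self, kinetic):
        t = np.arange(0.0, 20.0, 0.05)
        po = cc.popen_dynamic(np.full_like(t, 1.0), np.full_like(t, 50.0), t,
                              kinetic)
        assert np.abs(po - po[0]).max() < 1e-9

    def test_occupancy_simplex_preserved_over_100ms(self, kinetic):
        t = np.arange(0.0, 100.0, 0.02)
        c = 10.0 * np.exp(-t / 5.0) + 0.1
        v = np.where((t > 1) & (t < 1.8), -60.0, 70.0)
        po = cc.popen_dynamic(c, v, t, kinetic)  # raises if drift > 1e-6
        assert np.all((po >= 0.0) & (po <= 1.0))

    def test_step_decay_matches_generator_mode(self, kinetic):
        """A 10→0.1 µM step at the test potential decays with a τ close
        to the slowest open-weighted generator mode at (70 mV, 0.1 µM)."""
        t = np.arange(0.0, 80.0, 0.02)
        c = np.where(t < 1e-9, 10.0, 0.1)
        v = np.full_like(t, 70.0)
        init = equilibrium_occupancy(70.0, 10.0, kinetic.steady)
        po = cc.popen_dynamic(c, v, t, kinetic, init=init)
        trace = cc.PopenTrace(times=t, values=po).fit_decay()
        tau_mode = cc.deactivation_tau(kinetic, 70.0, 0.1)
        assert trace.tau_decay == pytest.approx(tau_mode, rel=0.10)

    def test_ode_backend_agrees_with_expm(self, kinetic):
        t = np.arange(0.0, 10.0, 0.05)
        c = 5.0 * np.exp(-t / 2.0) + 0.1
        v = np.full_like(t, 70.0)
        a = cc.popen_dynamic(c, v, t, kinetic, method="expm")
        b = cc.popen_dynamic(c, v, t, kinetic, method="ode")
        assert np.abs(a - b).max() < 1e-4


class TestSurfaceAverage:
    def _field(self, cs, ws):
        return cc.ConcentrationField(
            node_positions=np.arange(len(cs), dtype=float),
            free_ca=np.asarray(cs, dtype=float),
            membrane_nodes=np.arange(len(cs)),
            membrane_weights=np.asarray(ws, dtype=float),
        )

    def test_uniform_field_equals_pointwise(self, steady):
        f = self._field([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert cc.popen_surface_average(f, 50.0, steady) == pytest.approx(
            cc.popen_steady(50.0, 2.0, steady), rel=1e-12
        )

    def test_equal_weight_mean(self, steady):
        f = self._field([0.5, 5.0], [1.0, 1.0])
        po = 0.5 * (cc.popen_steady(60.0, 0.5, steady)
                    + cc.popen_steady(60.0, 5.0, steady))
        assert cc.popen_surface_average(f, 60.0, steady) == \
            pytest.approx(po, rel=1e-12)

    def test_bounded_by_extremes_and_empty_errors(self, steady,
                                                  pipette_geometry):
        field = cc.solve_stationary(pipette_geometry,
                                    cc.PumpParams(cycle_rate=5000.0), 10.0,
                                    n_r=40, n_x=96)
        c_mem = field.free_ca[field.membrane_nodes]
        po = cc.popen_surface_average(field, 100.0, steady)
        lo = cc.popen_steady(100.0, float(c_mem.min()), steady)
        hi = cc.popen_steady(100.0, float(c_mem.max()), steady)
        assert lo <= po <= hi
        empty = self._field([], [])
        with pytest.raises(ValueError):
            cc.popen_surface_average(empty, 100.0, steady)


def test_gating_state_validation():
    with pytest.raises(ValueError):
        cc.GatingState(np.ones(N_STATES))
    occ = np.zeros(N_STATES)
    occ[0] = 1.0
    assert cc.GatingState(occ).p_open == 0.0
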