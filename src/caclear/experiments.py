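"""Composed in-silico experiments.

``run_steady_experiment`` reproduces the pipette-infusion protocol: solve
the stationary field at fixed pipette Ca²⁺, average the equilibrium BK
open probability over the membrane per test voltage, normalize and fit a
Boltzmann function.

``run_pulse_experiment`` reproduces the pulsed-influx protocol: integrate
the dynamic reaction-diffusion problem, feed the membrane-adjacent Ca²⁺
time course and the command-voltage trace into the kinetic 10-state BK
model, and fit a mono-exponential to the post-pulse decay of P_open.

``scan_pump_rates`` repeats either experiment over a grid of pump cycle
rates and reports the smallest rate meeting the respective criterion
(activation-curve overlay within tolerance of the resting-Ca²⁺
calibration; τ_decay within a target band).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .fits import ActivationCurve, FitFailure, PopenTrace
from .field import solve_dynamic, wellmixed_reference
from .gating import (
    BKKineticParams,
    BKSteadyParams,
    equilibrium_occupancy,
    popen_dynamic,
    popen_surface_average,
    steady_activation_curve,
)
from .params import BufferParams, CellGeometry, InfluxProtocol, PumpParams
from .stationary import solve_stationary

DEFAULT_V_GRID = np.arange(-80.0, 201.0, 10.0)  # mV, the recording protocol


def run_steady_experiment(
    geometry: CellGeometry,
    pump: PumpParams,
    bk_steady: BKSteadyParams,
    c_pip: float = 10.0,
    v_grid: np.ndarray = DEFAULT_V_GRID,
    d_ca: float = 220.0,
    n_r: int = 80,
    n_x: int = 192,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ActivationCurve:
    """Computed activation curve under pipette infusion with pumps."""
    v_grid = np.asarray(v_grid, dtype=float)
    if pump.cycle_rate == 0.0:
        # no pump, no leak: uniform field at the pipette value
        po = steady_activation_curve(bk_steady, c_pip, v_grid, constants)
        curve = ActivationCurve(voltages=v_grid, g_norm=po, c_uM=c_pip)
        return curve.fit()
    field = solve_stationary(
        geometry, pump, c_pip, d_ca=d_ca, n_r=n_r, n_x=n_x
    )
    po = popen_surface_average(field, v_grid, bk_steady, constants)
    curve = ActivationCurve(voltages=v_grid, g_norm=po / po.max(), c_uM=c_pip)
    return curve.fit()


@dataclass
class PulseResult:
    """Pulse-experiment output: the P_open trace (with τ fit) plus the
    underlying concentration summaries."""

    trace: PopenTrace
    times: np.ndarray
    c_membrane: np.ndarray
    c_volume: np.ndarray
    end_of_pulse_c_volume: float


def run_pulse_experiment(
    geometry: CellGeometry,
    pump: PumpParams,
    buffer: BufferParams,
    protocol: InfluxProtocol,
    bk_kinetic: BKKineticParams,
    d_ca: float = 220.0,
    n_shells: int = 48,
    readout: str = "membrane",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> PulseResult:
    """Simulate the BK response to the pulsed Ca²⁺ influx and fit τ_decay.

    ``readout`` selects the concentration driving the channels:
    'membrane' (membrane-adjacent shell; channels are membrane proteins)
    or 'volume' (volume average).
    """
    series = solve_dynamic(
        geometry, pump, buffer, protocol, d_ca=d_ca, n_shells=n_shells
    )
    t = series.times
    if readout == "membrane":
        c_drive = series.c_membrane
    elif readout == "volume":
        c_drive = series.c_volume
    else:
        raise ValueError("readout must be 'membrane' or 'volume'")
    v_drive = np.array([protocol.voltage_at(tt) for tt in t])
    init = equilibrium_occupancy(
        protocol.test_potential, pump.resting_c0, bk_kinetic.steady, constants
    )
    po = popen_dynamic(c_drive, v_drive, t, bk_kinetic, init=init,
                       constants=constants)
    trace = PopenTrace(times=t, values=po, protocol_tag=f"pulse x{protocol.n_pulses}")
    try:
        trace.fit_decay(t_min=protocol.last_pulse_end)
    except FitFailure:
        pass  # tau_decay stays None (persistent / non-decaying response)
    i_end = int(np.argmin(np.abs(t - protocol.last_pulse_end)))
    return PulseResult(
        trace=trace,
        times=t,
        c_membrane=series.c_membrane,
        c_volume=series.c_volume,
        end_of_pulse_c_volume=float(series.c_volume[i_end]),
    )


@dataclass
class RateScanResult:
    rates: np.ndarray
    mode: str
    values: np.ndarray  # V_h (mV) in steady mode, τ_decay (ms) in pulse mode
    reference: float  # V_h of the c₀ calibration curve, or τ target
    tolerance: float
    minimal_sufficient_rate: float | None

    def to_frame(self):
        import pandas as pd

        col = "vh_mV" if self.mode == "steady" else "tau_decay_ms"
        return pd.DataFrame({"cycle_rate_per_s": self.rates, col: self.values})


def scan_pump_rates(
    rates,
    mode: str,
    geometry: CellGeometry,
    pump: PumpParams,
    bk_steady: BKSteadyParams | None = None,
    bk_kinetic: BKKineticParams | None = None,
    buffer: BufferParams | None = None,
    protocol: InfluxProtocol | None = None,
    c_pip: float = 10.0,
    v_grid: np.ndarray = DEFAULT_V_GRID,
    overlay_tolerance_mV: float = 10.0,
    tau_target_ms: float | None = None,
    tau_band: float = 0.3,
    d_ca: float = 220.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> RateScanResult:
    """Run the steady or pulse experiment over pump cycle rates.

    steady mode: reference is the fitted V_h of the uniform c₀ activation
    curve; the minimal sufficient rate is the smallest rate whose curve
    lands within ``overlay_tolerance_mV`` of that reference.
    pulse mode: the minimal sufficient rate is the smallest rate whose
    fitted τ_decay lies within ``tau_band`` (relative) of
    ``tau_target_ms``.
    """
    rates = np.asarray(list(rates), dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two rates")
    values = np.empty(rates.size)

    if mode == "steady":
        if bk_steady is None:
            raise ValueError("steady mode needs bk_steady")
        cal = ActivationCurve(
            voltages=v_grid,
            g_norm=steady_activation_curve(bk_steady, pump.resting_c0, v_grid,
                                           constants),
            c_uM=pump.resting_c0,
        ).fit()
        reference = cal.fitted_vh
        for i, r in enumerate(rates):
            curve = run_steady_experiment(
                geometry, replace(pump, cycle_rate=float(r)), bk_steady,
                c_pip=c_pip, v_grid=v_grid, d_ca=d_ca, constants=constants,
            )
            values[i] = curve.fitted_vh
        ok = np.abs(values - reference) <= overlay_tolerance_mV
        minimal = float(rates[ok].min()) if ok.any() else None
        return RateScanResult(rates, mode, values, reference,
                              overlay_tolerance_mV, minimal)

    if mode == "pulse":
        if bk_kinetic is None or protocol is None:
            raise ValueError("pulse mode needs bk_kinetic and protocol")
        buffer = buffer if buffer is not None else BufferParams(b_total=0.0)
        for i, r in enumerate(rates):
            res = run_pulse_experiment(
                geometry, replace(pump, cycle_rate=float(r)), buffer,
                protocol, bk_kinetic, d_ca=d_ca, constants=constants,
            )
            values[i] = np.nan if res.trace.tau_decay is None else res.trace.tau_decay
        minimal = None
        if tau_target_ms is not None:
            ok = np.isfinite(values) & (
                np.abs(values - tau_target_ms) <= tau_band * tau_target_ms
            )
            minimal = float(rates[ok].min()) if ok.any() else None
        return RateScanResult(rates, mode, values,
                              tau_target_ms if tau_target_ms else np.nan,
                              tau_band, minimal)

    raise ValueError("mode must be 'steady' or 'pulse'")
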