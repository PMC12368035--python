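"""Calibration of the 10-state BK gating model, statsmodels-style.

Two Model classes are provided, each built from data with ``fit()``
returning a Results object carrying estimates, diagnostics and a
``summary()`` table:

* :class:`BKSteadyCalibration` — fits the equilibrium parameters
  (L(0), gating charge, closed/open dissociation constants) to
  activation curves recorded at several fixed Ca²⁺ concentrations.
* :class:`BKKineticCalibration` — with the equilibrium constants pinned,
  fits the rate-scale parameters (per-tier opening rates, charge split,
  per-site Ca²⁺ on-rate) to open-probability responses to fast Ca²⁺
  switches at constant voltage.

Both use bounded nonlinear least squares with seeded Latin-hypercube
multi-starts; individual dissociation constants can be degenerate (four
curves cannot pin ten constants uniquely), so quality is judged on
predicted curves and V_h(c), which the Results objects report.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.linalg import eig
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .fits import fit_boltzmann
from .gating import (
    BKKineticParams,
    BKSteadyParams,
    build_generator,
    deactivation_tau,
    equilibrium_occupancy,
    steady_activation_curve,
)


class NonIdentifiableError(ValueError):
    """Dataset cannot constrain the requested parameters."""


@dataclass
class SteadyCurveData:
    """One activation curve at fixed pipette Ca²⁺."""

    c_uM: float
    voltages: np.ndarray
    g_norm: np.ndarray


@dataclass
class SwitchTraceData:
    """One constant-voltage response to an instantaneous Ca²⁺ switch."""

    c_from: float
    c_to: float
    v_hold: float
    times: np.ndarray  # ms
    values: np.ndarray  # P_open surrogate


def popen_after_switch(
    p: BKKineticParams,
    c_from: float,
    c_to: float,
    v_hold: float,
    times: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Closed-form P_open(t) after an instantaneous c_from→c_to switch at
    constant voltage, via eigen-decomposition of the (constant) generator."""
    times = np.asarray(times, dtype=float)
    p0 = equilibrium_occupancy(v_hold, c_from, p.steady, constants).occupancy
    G = build_generator(v_hold, c_to, p, constants)
    lam, V = eig(G.T)
    coef = np.linalg.solve(V, p0.astype(complex))
    # occupancies at all times: V @ (coef * exp(lam t))
    et = np.exp(np.outer(times * 1e-3, lam))  # (nt, 10); rates are s⁻¹
    occ = (V[None, :, :] * (coef * et)[:, None, :]).sum(axis=2).real
    return np.clip(occ[:, 5:].sum(axis=1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# steady calibration
# ---------------------------------------------------------------------------

_STEADY_LOG_BOUNDS = {
    "l0": (1.0, 8.0),  # log10
    "q": (0.5, 3.0),  # linear, elementary charges
    "k": (-1.5, 3.0),  # log10 µM, each of kc1..4, ko1..4
}


@dataclass
class BKSteadyCalibrationResults:
    params: BKSteadyParams
    rmse: float
    per_curve_rmse: dict[float, float]
    fitted_vh: dict[float, float]
    n_starts: int
    start_costs: np.ndarray
    converged: bool

    def predict(self, c: float, voltages: np.ndarray) -> np.ndarray:
        return steady_activation_curve(self.params, c, voltages)

    def summary(self) -> str:
        lines = [
            "BK steady-state gating calibration",
            "==================================",
            f"L(0)            {self.params.l0:12.4g}",
            f"gating charge Q {self.params.gating_charge_q:12.4g} e",
            f"K_C (µM)        " + "  ".join(f"{k:.4g}" for k in self.params.kc),
            f"K_O (µM)        " + "  ".join(f"{k:.4g}" for k in self.params.ko),
            f"overall RMSE    {self.rmse:12.4g}",
            f"multi-starts    {self.n_starts} (best cost {self.start_costs.min():.4g})",
            "per-curve:   c (µM)     RMSE      V_h (mV)",
        ]
        for c in sorted(self.per_curve_rmse):
            lines.append(
                f"           {c:8.3g}  {self.per_curve_rmse[c]:9.3g}"
                f"  {self.fitted_vh[c]:9.2f}"
            )
        lines.append("note: individual K_C/K_O values may be degenerate; "
                     "judge fits on curves and V_h(c).")
        return "\n".join(lines)


class BKSteadyCalibration:
    """Model: equilibrium BK parameters from activation curves.

    Parameters
    ----------
    curves : list of :class:`SteadyCurveData`
        Activation curves at ≥ 2 distinct Ca²⁺ concentrations.
    """

    def __init__(self, curves: list[SteadyCurveData],
                 constants: PhysicalConstants = DEFAULT_CONSTANTS):
        if len({round(cu.c_uM, 9) for cu in curves}) < 2:
            raise NonIdentifiableError(
                "activation curves at a single Ca²⁺ concentration cannot "
                "separate L(0) from the binding constants; provide >= 2 "
                "distinct concentrations"
            )
        self.curves = curves
        self.constants = constants

    @classmethod
    def from_dataframe(cls, df, constants: PhysicalConstants = DEFAULT_CONSTANTS):
        """Build from a long-format table with columns
        c_uM, voltage_mV, g_norm."""
        curves = []
        for c, sub in df.groupby("c_uM"):
            sub = sub.sort_values("voltage_mV")
            curves.append(SteadyCurveData(
                c_uM=float(c),
                voltages=sub["voltage_mV"].to_numpy(),
                g_norm=sub["g_norm"].to_numpy(),
            ))
        return cls(curves, constants)

    def _unpack(self, x: np.ndarray) -> BKSteadyParams:
        return BKSteadyParams(
            l0=10.0 ** x[0],
            gating_charge_q=x[1],
            kc=tuple(10.0 ** x[2:6]),
            ko=tuple(10.0 ** x[6:10]),
        )

    def _residual(self, x: np.ndarray) -> np.ndarray:
        p = self._unpack(x)
        out = []
        for cu in self.curves:
            out.append(
                steady_activation_curve(p, cu.c_uM, cu.voltages, self.constants)
                - cu.g_norm
            )
        return np.concatenate(out)

    def fit(self, n_starts: int = 32, seed: int = 1) -> BKSteadyCalibrationResults:
        lb = np.array([_STEADY_LOG_BOUNDS["l0"][0], _STEADY_LOG_BOUNDS["q"][0]]
                      + [_STEADY_LOG_BOUNDS["k"][0]] * 8)
        ub = np.array([_STEADY_LOG_BOUNDS["l0"][1], _STEADY_LOG_BOUNDS["q"][1]]
                      + [_STEADY_LOG_BOUNDS["k"][1]] * 8)
        sampler = qmc.LatinHypercube(d=lb.size, seed=seed)
        starts = lb + sampler.random(n_starts) * (ub - lb)
        best = None
        costs = np.full(n_starts, np.inf)
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(self._residual, x0, bounds=(lb, ub),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:  # pragma: no cover - defensive
                continue
            costs[i] = sol.cost
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:  # pragma: no cover
            raise RuntimeError("all starts failed")
        params = self._unpack(best.x)
        n_points = sum(cu.voltages.size for cu in self.curves)
        rmse = float(np.sqrt(2.0 * best.cost / n_points))
        per_curve = {}
        vh = {}
        for cu in self.curves:
            pred = steady_activation_curve(params, cu.c_uM, cu.voltages,
                                           self.constants)
            per_curve[cu.c_uM] = float(np.sqrt(np.mean((pred - cu.g_norm) ** 2)))
            vh[cu.c_uM] = fit_boltzmann(cu.voltages, pred)[0]
        return BKSteadyCalibrationResults(
            params=params, rmse=rmse, per_curve_rmse=per_curve, fitted_vh=vh,
            n_starts=n_starts, start_costs=costs, converged=bool(best.success),
        )


# ---------------------------------------------------------------------------
# kinetic calibration
# ---------------------------------------------------------------------------

@dataclass
class BKKineticCalibrationResults:
    params: BKKineticParams
    rms: float
    per_trace_rms: list[float]
    ca_on_rate_identifiable: bool
    large_residual_warning: bool
    n_starts: int
    start_costs: np.ndarray

    def predict(self, trace: SwitchTraceData,
                constants: PhysicalConstants = DEFAULT_CONSTANTS) -> np.ndarray:
        return popen_after_switch(self.params, trace.c_from, trace.c_to,
                                  trace.v_hold, trace.times, constants)

    def deactivation_tau(self, v: float, c: float) -> float:
        return deactivation_tau(self.params, v, c)

    def summary(self) -> str:
        p = self.params
        lines = [
            "BK kinetic (10-state) calibration",
            "=================================",
            "opening rates at 0 mV (s⁻¹ per tier): "
            + "  ".join(f"{a:.4g}" for a in p.opening_rate0),
            "closing rates at 0 mV (s⁻¹, derived): "
            + "  ".join(f"{b:.4g}" for b in p.closing_rate0),
            f"charge split     {p.charge_split:8.3f}",
            f"Ca on-rate       {p.ca_on_rate:8.4g} µM⁻¹s⁻¹"
            + ("" if self.ca_on_rate_identifiable else "  [UNIDENTIFIABLE]"),
            f"response RMS     {self.rms:8.4g}",
            f"multi-starts     {self.n_starts}",
        ]
        if self.large_residual_warning:
            lines.append("warning: residuals large — traces may be "
                         "inconsistent with the pinned equilibria.")
        return "\n".join(lines)


class BKKineticCalibration:
    """Model: rate-scale parameters from Ca²⁺-switch responses, with the
    equilibrium constants pinned to a fixed steady parameter set."""

    def __init__(self, traces: list[SwitchTraceData], steady: BKSteadyParams,
                 constants: PhysicalConstants = DEFAULT_CONSTANTS):
        if len(traces) < 2:
            raise NonIdentifiableError("need at least two switch traces")
        self.traces = traces
        self.steady = steady
        self.constants = constants
        self.ca_identifiable = any(t.c_from != t.c_to for t in traces)

    def _unpack(self, x: np.ndarray) -> BKKineticParams:
        return BKKineticParams(
            steady=self.steady,
            opening_rate0=tuple(10.0 ** x[0:5]),
            charge_split=x[5],
            ca_on_rate=10.0 ** x[6],
        )

    def _residual(self, x: np.ndarray) -> np.ndarray:
        p = self._unpack(x)
        out = []
        for tr in self.traces:
            out.append(
                popen_after_switch(p, tr.c_from, tr.c_to, tr.v_hold, tr.times,
                                   self.constants) - tr.values
            )
        return np.concatenate(out)

    def fit(self, n_starts: int = 8, seed: int = 1) -> BKKineticCalibrationResults:
        # log10 opening rates (5), charge split, log10 ca_on_rate
        lb = np.array([-3.0] * 5 + [0.05, 0.5])
        ub = np.array([6.0] * 5 + [0.95, 4.0])
        sampler = qmc.LatinHypercube(d=lb.size, seed=seed)
        starts = lb + sampler.random(n_starts) * (ub - lb)
        best = None
        costs = np.full(n_starts, np.inf)
        for i, x0 in enumerate(starts):
            try:
                sol = least_squares(self._residual, x0, bounds=(lb, ub),
                                    xtol=1e-12, ftol=1e-12)
            except Exception:  # pragma: no cover
                continue
            costs[i] = sol.cost
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:  # pragma: no cover
            raise RuntimeError("all starts failed")
        params = self._unpack(best.x)
        per_rms = []
        for tr in self.traces:
            pred = popen_after_switch(params, tr.c_from, tr.c_to, tr.v_hold,
                                      tr.times, self.constants)
            per_rms.append(float(np.sqrt(np.mean((pred - tr.values) ** 2))))
        n_points = sum(tr.times.size for tr in self.traces)
        rms = float(np.sqrt(2.0 * best.cost / n_points))
        scale = max(float(np.max(np.abs(tr.values)))
                    for tr in self.traces) or 1.0
        return BKKineticCalibrationResults(
            params=params, rms=rms, per_trace_rms=per_rms,
            ca_on_rate_identifiable=self.ca_identifiable,
            large_residual_warning=rms > 0.1 * scale,
            n_starts=n_starts, start_costs=costs,
        )
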