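"""Trace and curve analysis: Boltzmann activation fits, mono-exponential
decay fits, and immunogold replica density quantification."""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import least_squares


class FitFailure(RuntimeError):
    """Fit did not improve on a trivial model or the data are unsuitable."""


@dataclass
class ActivationCurve:
    """Normalized conductance vs. voltage, optionally with a Boltzmann fit.

    fitted_vh/fitted_k are the half-activation voltage and slope factor
    (both mV) of g = 1/(1 + exp((V_h − V)/k)).
    """

    voltages: np.ndarray
    g_norm: np.ndarray
    c_uM: float | None = None
    fitted_vh: float | None = None
    fitted_k: float | None = None
    fit_rmse: float | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.g_norm = np.asarray(self.g_norm, dtype=float)
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")
        if self.voltages.shape != self.g_norm.shape:
            raise ValueError("voltages and g_norm must match")

    def fit(self) -> "ActivationCurve":
        vh, k, rmse = fit_boltzmann(self.voltages, self.g_norm)
        self.fitted_vh, self.fitted_k, self.fit_rmse = vh, k, rmse
        return self


@dataclass
class PopenTrace:
    """Open-probability (current surrogate) vs. time, with decay fit."""

    times: np.ndarray  # ms
    values: np.ndarray
    protocol_tag: str = ""
    tau_decay: float | None = None  # ms
    fit_window: tuple[float, float] | None = None
    fit_amplitude: float | None = None
    fit_baseline: float | None = None
    fit_rmse: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must match")

    def fit_decay(self, window: tuple[float, float] | None = None,
                  t_min: float | None = None) -> "PopenTrace":
        """Fit a·exp(−t/τ)+b on ``window`` (default: from the trace maximum
        after ``t_min`` to the end)."""
        if window is None:
            mask = self.times >= (self.times[0] if t_min is None else t_min)
            i0 = np.flatnonzero(mask)[np.argmax(self.values[mask])]
            window = (float(self.times[i0]), float(self.times[-1]))
        m = (self.times >= window[0]) & (self.times <= window[1])
        y = self.values[m]
        # persistent response: the signal has not even decayed to half its
        # peak by the end of the record — a mono-exponential τ would be
        # meaningless (dominated by whatever small early relaxation exists)
        if y.size and y[-1] > 0.5 * y.max():
            raise FitFailure("persistent (non-decaying) response")
        tau, a, b, rmse = fit_monoexponential(self.times, self.values, window)
        self.tau_decay, self.fit_amplitude, self.fit_baseline = tau, a, b
        self.fit_rmse, self.fit_window = rmse, window
        return self


@dataclass(frozen=True)
class DensityEstimate:
    """Particle count over area; density is the exact ratio (µm⁻²)."""

    particle_count: float
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.particle_count < 0:
            raise ValueError("particle_count must be >= 0")

    @property
    def density(self) -> float:
        return self.particle_count / self.area


def em_density(count: float, area: float) -> DensityEstimate:
    """Immunogold surface density: gold particles divided by surface area."""
    return DensityEstimate(particle_count=count, area=area)


def aggregate_density(estimates: list[DensityEstimate]) -> tuple[float, float]:
    """Mean ± SEM of per-structure densities (the study's summary form)."""
    d = np.array([e.density for e in estimates])
    sem = d.std(ddof=1) / math.sqrt(d.size) if d.size > 1 else 0.0
    return float(d.mean()), float(sem)


def pooled_density(estimates: list[DensityEstimate]) -> float:
    """Total count over total area (Poisson-efficient pooled estimator)."""
    tot_n = sum(e.particle_count for e in estimates)
    tot_a = sum(e.area for e in estimates)
    return tot_n / tot_a


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

def fit_boltzmann(voltages, g_norm) -> tuple[float, float, float]:
    """Least-squares Boltzmann fit g = 1/(1 + exp((V_h − V)/k)).

    Returns (V_h, k, rmse); raises :class:`FitFailure` when the sigmoid
    does not beat a constant model (flat or non-sigmoidal input).
    """
    v = np.asarray(voltages, dtype=float)
    g = np.asarray(g_norm, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 points spanning the transition")

    def resid(p):
        vh, k = p
        return 1.0 / (1.0 + np.exp((vh - v) / k)) - g

    # initial guess: half-crossing and 25%-75% span
    gmax = g.max()
    half = 0.5 * gmax
    vh0 = float(v[np.argmin(np.abs(g - half))])
    span = float(np.ptp(v))
    best = None
    for k0 in (span / 20.0, span / 8.0, span / 3.0):
        sol = least_squares(resid, [vh0, k0],
                            bounds=([v.min() - 5 * span, 1e-3],
                                    [v.max() + 5 * span, 10 * span]))
        if best is None or sol.cost < best.cost:
            best = sol
    rmse = math.sqrt(2.0 * best.cost / v.size)
    const_rmse = float(g.std())
    if not (rmse < 0.8 * const_rmse or rmse < 1e-6):
        raise FitFailure("Boltzmann fit no better than a constant model")
    vh, k = best.x
    return float(vh), float(k), rmse


def fit_monoexponential(times, values, window) -> tuple[float, float, float, float]:
    """Fit a·exp(−(t−t₀)/τ) + b on ``window`` = (t₀, t₁) in ms.

    Initialized from a log-linear regression on the baseline-subtracted
    early decay.  Returns (tau_ms, amplitude, baseline, rmse); raises
    :class:`FitFailure` for non-decaying windows.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    t0, t1 = window
    m = (t >= t0) & (t <= t1)
    tt = t[m] - t0
    yy = y[m]
    if tt.size < 10:
        raise ValueError("window must contain at least 10 samples")
    if yy[0] <= yy[-1] + 1e-12 and yy.max() <= yy[0] + 1e-12:
        raise FitFailure("window is not decaying")

    b0 = float(yy[-1])
    amp0 = float(yy[0] - b0)
    if amp0 <= 0:
        raise FitFailure("window is not decaying")
    # log-linear init on the upper part of the decay
    pos = yy - b0 > 0.05 * amp0
    if pos.sum() >= 3:
        slope = np.polyfit(tt[pos], np.log(yy[pos] - b0), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (tt[-1] - tt[0]) / 3.0
    else:  # pragma: no cover
        tau0 = (tt[-1] - tt[0]) / 3.0
    tau0 = min(max(tau0, 1e-3), 10 * (tt[-1] + 1e-9))

    def resid(p):
        a, tau, b = p
        return a * np.exp(-tt / tau) + b - yy

    sol = least_squares(
        resid, [amp0, tau0, b0],
        bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
    )
    a, tau, b = sol.x
    rmse = math.sqrt(2.0 * sol.cost / tt.size)
    if a < 1e-12:
        raise FitFailure("no decaying component found")
    return float(tau), float(a), float(b), rmse


def loglinear_tau(times, values, baseline, window) -> float:
    """Independent τ estimate: ordinary log-linear regression of the
    baseline-subtracted decay (oracle for the nonlinear fit)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float) - baseline
    t0, t1 = window
    m = (t >= t0) & (t <= t1) & (y > 0)
    slope = np.polyfit(t[m], np.log(y[m]), 1)[0]
    return -1.0 / slope
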