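"""Ten-state gating model of the large-conductance Ca²⁺- and
voltage-activated K⁺ (BK) channel.

The channel occupies five closed (C₀..C₄) and five open (O₀..O₄) states,
the index counting occupied Ca²⁺-binding sites (four sites total).
Horizontal transitions (binding/unbinding) depend on the local free Ca²⁺
concentration; vertical transitions (closed↔open) carry the gating charge
and depend on voltage.  At equilibrium the open probability has the closed
form

    P_open = 1 / (1 + B(c) · L(0) · exp(−Q·F·V/(R·T)))

where L(0) is the closed/open equilibrium constant at 0 mV with no Ca²⁺
bound and B(c) is the ratio of the closed- and open-state binding
polynomials in c with dissociation constants K_C1..K_C4 and K_O1..K_O4.
Because the open states bind Ca²⁺ more tightly (K_O < K_C), raising c
tilts the equilibrium toward open and shifts activation leftward.

The kinetic extension assigns per-tier opening/closing rates at 0 mV with
a symmetric charge split across the transition barrier and a single
per-site Ca²⁺ on-rate with statistical factors; unbinding rates follow
from the dissociation constants, which makes every 4-cycle of the scheme
obey detailed balance by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

N_STATES = 10  # C0..C4 then O0..O4
N_SITES = 4


@dataclass(frozen=True)
class BKSteadyParams:
    """Equilibrium-constant form of the 10-state model.

    l0 : closed/open equilibrium constant at 0 mV, zero Ca²⁺ bound.
    gating_charge_q : effective gating charge, elementary charges.
    kc, ko : Ca²⁺ dissociation constants (µM) of the four closed- and
        open-state binding steps.
    """

    l0: float
    gating_charge_q: float
    kc: tuple[float, float, float, float]
    ko: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.l0 <= 0 or self.gating_charge_q <= 0:
            raise ValueError("l0 and gating_charge_q must be positive")
        if len(self.kc) != N_SITES or len(self.ko) != N_SITES:
            raise ValueError("kc and ko must each hold four constants")
        if any(k <= 0 for k in self.kc) or any(k <= 0 for k in self.ko):
            raise ValueError("dissociation constants must be positive")

    def tier_l0(self, i: int) -> float:
        """Closed/open equilibrium constant of tier i at 0 mV:
        L(0)·∏_{j<=i} K_Oj/K_Cj (open states bind tighter, so deeper
        tiers favour open)."""
        out = self.l0
        for j in range(i):
            out *= self.ko[j] / self.kc[j]
        return out

    def to_dict(self) -> dict:
        return {
            "l0": self.l0,
            "gating_charge_q": self.gating_charge_q,
            "kc": list(self.kc),
            "ko": list(self.ko),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BKSteadyParams":
        return cls(
            l0=d["l0"],
            gating_charge_q=d["gating_charge_q"],
            kc=tuple(d["kc"]),
            ko=tuple(d["ko"]),
        )


@dataclass(frozen=True)
class BKKineticParams:
    """Rate-constant form; equilibria pinned to an embedded steady set.

    opening_rate0 : C_i→O_i rates at 0 mV, s⁻¹, one per tier (i = 0..4).
    charge_split : fraction of the gating charge acting on the opening
        rate (the remainder, with opposite sign, on the closing rate).
    ca_on_rate : per-free-site Ca²⁺ binding rate, µM⁻¹ s⁻¹; the C_i→C_{i+1}
        (and O_i→O_{i+1}) rate is (4−i)·ca_on_rate·c and the matching
        unbinding rate (4−i)·ca_on_rate·K so each horizontal equilibrium
        equals c/K with the macroscopic dissociation constant K.
    """

    steady: BKSteadyParams
    opening_rate0: tuple[float, float, float, float, float]
    charge_split: float = 0.5
    ca_on_rate: float = 500.0

    def __post_init__(self) -> None:
        if len(self.opening_rate0) != 5:
            raise ValueError("opening_rate0 needs five per-tier rates")
        if any(a <= 0 for a in self.opening_rate0):
            raise ValueError("opening rates must be positive")
        if not (0.0 <= self.charge_split <= 1.0):
            raise ValueError("charge_split must lie in [0, 1]")
        if self.ca_on_rate < 0:
            raise ValueError("ca_on_rate must be >= 0")

    @property
    def closing_rate0(self) -> tuple[float, ...]:
        """O_i→C_i rates at 0 mV, derived so that β_i/α_i equals the
        tier equilibrium constant (detailed balance by construction)."""
        return tuple(
            a * self.steady.tier_l0(i) for i, a in enumerate(self.opening_rate0)
        )

    def to_dict(self) -> dict:
        return {
            "steady": self.steady.to_dict(),
            "opening_rate0": list(self.opening_rate0),
            "charge_split": self.charge_split,
            "ca_on_rate": self.ca_on_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BKKineticParams":
        return cls(
            steady=BKSteadyParams.from_dict(d["steady"]),
            opening_rate0=tuple(d["opening_rate0"]),
            charge_split=d["charge_split"],
            ca_on_rate=d["ca_on_rate"],
        )


@dataclass
class GatingState:
    """Occupancy vector over (C₀..C₄, O₀..O₄)."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (N_STATES,):
            raise ValueError("occupancy must have 10 entries")
        if occ.min() < -1e-10 or abs(occ.sum() - 1.0) > 1e-10:
            raise ValueError("occupancy must be a probability vector")
        self.occupancy = occ

    @property
    def p_open(self) -> float:
        return float(self.occupancy[5:].sum())


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def b_factor(c, p: BKSteadyParams):
    """Ca²⁺-dependent factor B(c): closed-state binding polynomial over
    open-state binding polynomial (both quartic in c)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")

    def poly(kset):
        tot = np.ones_like(c)
        term = np.ones_like(c)
        for k in kset:
            term = term * c / k
            tot = tot + term
        return tot

    out = poly(p.kc) / poly(p.ko)
    return out if out.ndim else float(out)


def popen_steady(
    v, c, p: BKSteadyParams, constants: PhysicalConstants = DEFAULT_CONSTANTS
):
    """Equilibrium open probability at voltage ``v`` (mV) and free Ca²⁺
    ``c`` (µM)."""
    v = np.asarray(v, dtype=float)
    expo = -p.gating_charge_q * constants.faraday_over_RT_per_mV * v
    out = 1.0 / (1.0 + b_factor(c, p) * p.l0 * np.exp(expo))
    return out if out.ndim else float(out)


def equilibrium_occupancy(
    v: float, c: float, p: BKSteadyParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> GatingState:
    """Closed-form equilibrium occupancy over all ten states."""
    rel_c = np.ones(5)
    rel_o = np.ones(5)
    for i in range(N_SITES):
        rel_c[i + 1] = rel_c[i] * c / p.kc[i]
        rel_o[i + 1] = rel_o[i] * c / p.ko[i]
    expo = -p.gating_charge_q * constants.faraday_over_RT_per_mV * v
    c0_over_o0 = p.l0 * np.exp(expo)
    occ = np.concatenate([rel_c * c0_over_o0, rel_o])
    return GatingState(occ / occ.sum())


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def build_generator(
    v: float, c: float, p: BKKineticParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """10×10 rate generator G (s⁻¹) with G[i, j] the i→j rate; rows sum
    to zero.  State order: C₀..C₄ then O₀..O₄."""
    if c < 0:
        raise ValueError("concentration must be >= 0")
    s = p.steady
    x = p.charge_split
    phi = s.gating_charge_q * constants.faraday_over_RT_per_mV * v
    G = np.zeros((N_STATES, N_STATES))
    beta0 = p.closing_rate0
    for i in range(5):
        alpha = p.opening_rate0[i] * np.exp(x * phi)  # C_i -> O_i
        beta = beta0[i] * np.exp(-(1.0 - x) * phi)  # O_i -> C_i
        G[i, 5 + i] = alpha
        G[5 + i, i] = beta
    for i in range(N_SITES):
        kon = (N_SITES - i) * p.ca_on_rate
        G[i, i + 1] = kon * c
        G[i + 1, i] = kon * s.kc[i]
        G[5 + i, 5 + i + 1] = kon * c
        G[5 + i + 1, 5 + i] = kon * s.ko[i]
    np.fill_diagonal(G, 0.0)
    np.fill_diagonal(G, -G.sum(axis=1))
    return G


def stationary_distribution(G: np.ndarray) -> np.ndarray:
    """Probability vector p with p·G = 0 (null space of Gᵀ)."""
    _, _, vt = np.linalg.svd(G.T)
    p = np.abs(vt[-1])
    return p / p.sum()


def detailed_balance_cycles(
    p: BKKineticParams, v: float = 0.0, c: float = 1.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Products of clockwise/counter-clockwise rate ratios around the four
    C_i—C_{i+1}—O_{i+1}—O_i loops; all equal 1 under detailed balance."""
    G = build_generator(v, c, p, constants)
    out = np.empty(N_SITES)
    for i in range(N_SITES):
        a, b_, o_b, o_a = i, i + 1, 5 + i + 1, 5 + i
        fwd = G[a, b_] * G[b_, o_b] * G[o_b, o_a] * G[o_a, a]
        rev = G[a, o_a] * G[o_a, o_b] * G[o_b, b_] * G[b_, a]
        out[i] = fwd / rev
    return out


def deactivation_tau(
    p: BKKineticParams, v: float, c: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Relaxation time constant (ms) of the open-probability decay at
    fixed (v, c): the slowest generator mode with non-negligible
    projection on P_open, found from the eigen-decomposition of Gᵀ."""
    G = build_generator(v, c, p, constants)
    lam, V = np.linalg.eig(G.T)
    order = np.argsort(-lam.real)  # 0 first, then slowest
    # open-probability amplitude carried by each mode when starting open
    start = equilibrium_occupancy(v, 50.0, p.steady, constants).occupancy
    coef = np.linalg.solve(V, start.astype(complex))
    p_open_mask = np.zeros(N_STATES)
    p_open_mask[5:] = 1.0
    for idx in order[1:]:
        amp = abs((coef[idx] * V[:, idx] @ p_open_mask))
        if amp > 1e-4:
            return float(-1000.0 / lam[idx].real)
    return float(-1000.0 / lam[order[1]].real)  # pragma: no cover


def popen_dynamic(
    c_of_t: np.ndarray,
    v_of_t: np.ndarray,
    times: np.ndarray,
    p: BKKineticParams,
    init: GatingState | None = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    method: str = "expm",
) -> np.ndarray:
    """Propagate the master equation along piecewise-constant (v, c)
    sampled on ``times`` (ms); returns P_open at each time.

    ``method='expm'`` advances each interval with a matrix exponential at
    the midpoint inputs (exactly probability-conserving); ``method='ode'``
    integrates the linear ODE with BDF.  Repeated (v, c) pairs reuse the
    cached propagator, so long constant-input stretches cost one expm.
    """
    times = np.asarray(times, dtype=float)
    c_of_t = np.asarray(c_of_t, dtype=float)
    v_of_t = np.asarray(v_of_t, dtype=float)
    if not (times.shape == c_of_t.shape == v_of_t.shape):
        raise ValueError("times, c_of_t and v_of_t must share one grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if init is None:
        init = equilibrium_occupancy(v_of_t[0], c_of_t[0], p.steady, constants)
    occ = init.occupancy.copy()
    p_open = np.empty(times.size)
    p_open[0] = occ[5:].sum()

    if method == "expm":
        cache: dict[tuple[float, float, float], np.ndarray] = {}
        for k in range(times.size - 1):
            dt_s = (times[k + 1] - times[k]) * 1e-3
            vm = 0.5 * (v_of_t[k] + v_of_t[k + 1])
            cm = 0.5 * (c_of_t[k] + c_of_t[k + 1])
            key = (round(vm, 9), round(cm, 12), round(dt_s, 12))
            prop = cache.get(key)
            if prop is None:
                prop = expm(build_generator(vm, cm, p, constants).T * dt_s)
                cache[key] = prop
            occ = prop @ occ
            occ = np.clip(occ, 0.0, None)
            s = occ.sum()
            if abs(s - 1.0) > 1e-6:
                raise RuntimeError(f"normalization drift {s - 1.0:.2e}")
            occ /= s
            p_open[k + 1] = occ[5:].sum()
        return p_open

    if method == "ode":
        from scipy.interpolate import interp1d

        c_i = interp1d(times, c_of_t)
        v_i = interp1d(times, v_of_t)

        def rhs(t_ms, y):
            G = build_generator(float(v_i(t_ms)), max(float(c_i(t_ms)), 0.0),
                                p, constants)
            return (y @ G) * 1e-3  # rates are s⁻¹, t in ms

        sol = solve_ivp(rhs, (times[0], times[-1]), occ, t_eval=times,
                        method="BDF", rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise RuntimeError(f"gating integration failed: {sol.message}")
        occ_t = sol.y.T
        drift = np.abs(occ_t.sum(axis=1) - 1.0).max()
        if drift > 1e-6:
            raise RuntimeError(f"normalization drift {drift:.2e}")
        return occ_t[:, 5:].sum(axis=1)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# activation curves and surface averages
# ---------------------------------------------------------------------------

def steady_activation_curve(
    p: BKSteadyParams, c: float, v_grid: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Normalized conductance-voltage relation at fixed c: P_open over the
    voltage grid divided by its maximum (tail-current convention)."""
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("v_grid must be nonempty")
    po = popen_steady(v_grid, c, p, constants)
    return po / po.max()


def popen_surface_average(
    field, v, p: BKSteadyParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Area-weighted mean open probability over the membrane nodes of a
    concentration field, at voltage(s) ``v``."""
    idx = np.asarray(field.membrane_nodes)
    if idx.size == 0:
        raise ValueError("field has no membrane nodes")
    w = np.asarray(field.membrane_weights, dtype=float)
    c_mem = np.asarray(field.free_ca)[idx]
    v_arr = np.atleast_1d(np.asarray(v, dtype=float))
    po = popen_steady(v_arr[:, None], c_mem[None, :], p, constants)
    out = (po * w).sum(axis=-1) / w.sum()
    return out if np.ndim(v) else float(out[0])
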