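"""Parameter types shared by the diffusion solvers and gating models.

All parameter sets are frozen dataclasses that serialize to/from flat
key-value dictionaries (JSON-compatible) with keys exactly matching the
field names.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Type, TypeVar

from .constants import IONS_PER_UM_UM3

T = TypeVar("T", bound="_ParamBase")


class InvalidGeometryError(ValueError):
    """Raised when a cell geometry is physically inconsistent."""


@dataclass(frozen=True)
class _ParamBase:
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls: Type[T], d: dict[str, Any]) -> T:
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls: Type[T], path: str | Path) -> T:
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CellGeometry(_ParamBase):
    """Spherical cell with a diffusion-accessible volume fraction.

    Attributes
    ----------
    surface_area : float
        Membrane surface, µm².
    accessible_fraction : float
        Fraction of the geometric volume freely accessible to diffusion
        (the remainder is excluded by organelles/cytoskeleton).
    pipette_contact_radius : float
        Radius (µm) of the disc-equivalent pipette-cell contact patch;
        0 when no pipette is attached.
    """

    surface_area: float = 300.0
    accessible_fraction: float = 0.3
    pipette_contact_radius: float = 0.0

    def __post_init__(self) -> None:
        if self.surface_area <= 0:
            raise InvalidGeometryError("surface_area must be positive")
        if not (0.0 < self.accessible_fraction <= 1.0):
            raise InvalidGeometryError("accessible_fraction must be in (0, 1]")
        if self.pipette_contact_radius < 0:
            raise InvalidGeometryError("pipette_contact_radius must be >= 0")
        if self.pipette_contact_radius >= self.radius:
            raise InvalidGeometryError(
                "pipette_contact_radius must be smaller than the cell radius"
            )

    @property
    def radius(self) -> float:
        """Sphere radius (µm) derived from the surface area."""
        return math.sqrt(self.surface_area / (4.0 * math.pi))

    @property
    def volume(self) -> float:
        """Geometric volume, µm³."""
        return (4.0 / 3.0) * math.pi * self.radius**3

    @property
    def accessible_volume(self) -> float:
        """Diffusion-accessible volume, µm³."""
        return self.accessible_fraction * self.volume

    @property
    def pipette_cap_cos(self) -> float:
        """cos(θ₀) of the polar spherical cap whose area equals the
        disc of ``pipette_contact_radius`` (1.0 when no pipette)."""
        a, r = self.pipette_contact_radius, self.radius
        return 1.0 - a * a / (2.0 * r * r)

    @property
    def pipette_cap_area(self) -> float:
        """Area (µm²) of the pipette contact cap (= π·a²)."""
        return math.pi * self.pipette_contact_radius**2


def make_geometry(
    surface_area: float,
    accessible_fraction: float,
    pipette_contact_radius: float = 0.0,
) -> CellGeometry:
    """Build a :class:`CellGeometry` from a surface area.

    Raises :class:`InvalidGeometryError` on non-positive area or a pipette
    patch at least as large as the cell itself.
    """
    return CellGeometry(
        surface_area=surface_area,
        accessible_fraction=accessible_fraction,
        pipette_contact_radius=pipette_contact_radius,
    )


@dataclass(frozen=True)
class PumpParams(_ParamBase):
    """Plasma-membrane Ca²⁺ pump (PMCA-type) transport parameters.

    The pump efflux density is φ·ρ·f(c) with the Hill activity
    f(c) = cⁿ/(cⁿ + c_halfⁿ); one Ca²⁺ ion is extruded per cycle.

    Attributes
    ----------
    cycle_rate : float
        φ, full transport cycles per second of a single pump.
    density : float
        ρ, pumps per µm² of membrane.
    c_half : float
        Half-activation Ca²⁺ concentration of the Hill function, µM.
    hill_n : float
        Hill coefficient (dimensionless).
    resting_c0 : float
        Resting free Ca²⁺ concentration c₀ (µM) at which the constant
        leak influx exactly cancels the pump efflux.
    """

    cycle_rate: float = 5000.0
    density: float = 50.0
    c_half: float = 0.43
    hill_n: float = 2.0
    resting_c0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("density", "c_half", "hill_n", "resting_c0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cycle_rate < 0:
            raise ValueError("cycle_rate must be >= 0")


@dataclass(frozen=True)
class BufferParams(_ParamBase):
    """Mobile Ca²⁺ buffer (EGTA) with second-order binding kinetics.

    Values for the on/off rates are literature-typical EGTA kinetics at
    physiological pH, used as substitutes where the source constants are
    not printed; all are configurable.
    """

    b_total: float = 0.0  # µM; 0 or 10000 in the modelled conditions
    k_on: float = 2.7  # µM⁻¹ s⁻¹
    k_off: float = 0.4  # s⁻¹
    diff_coeff: float = 110.0  # µm²/s

    def __post_init__(self) -> None:
        for name in ("b_total", "k_on", "k_off", "diff_coeff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def k_d(self) -> float:
        """Dissociation constant k_off/k_on, µM (inf when k_on = 0)."""
        return self.k_off / self.k_on if self.k_on > 0 else math.inf

    def free_fraction_at(self, c: float) -> float:
        """Equilibrium free-buffer fraction at fixed free Ca²⁺ ``c``."""
        if self.k_on == 0 and self.k_off == 0:
            return 1.0
        return self.k_off / (self.k_off + self.k_on * c)


@dataclass(frozen=True)
class InfluxProtocol(_ParamBase):
    """Voltage-commanded Ca²⁺ influx pulse train.

    A depolarizing pre-step (no influx, no driving force) is followed by
    ``n_pulses`` brief repolarizations to ``pulse_potential`` during which a
    fixed number of ions enters through the voltage-gated Ca²⁺ channels;
    between and after pulses the membrane sits at ``test_potential`` where
    the K⁺-channel readout is measured.  Pulse k occupies the window
    [k·(pulse_duration+inter_pulse_gap), same + pulse_duration) in ms.
    """

    n_pulses: int = 1
    pulse_duration: float = 0.8  # ms
    inter_pulse_gap: float = 2.0  # ms
    ions_per_pulse: float = 1.2e6
    pre_potential: float = -90.0  # mV
    pulse_potential: float = -60.0  # mV
    test_potential: float = 70.0  # mV
    record_duration: float = 100.0  # ms

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.inter_pulse_gap < 0:
            raise ValueError("inter_pulse_gap must be >= 0")
        if self.ions_per_pulse <= 0:
            raise ValueError("ions_per_pulse must be positive")

    @property
    def period(self) -> float:
        """Pulse repetition period, ms."""
        return self.pulse_duration + self.inter_pulse_gap

    @property
    def total_influx_ions(self) -> float:
        return self.n_pulses * self.ions_per_pulse

    @property
    def last_pulse_end(self) -> float:
        """End time (ms) of the final influx pulse."""
        return (self.n_pulses - 1) * self.period + self.pulse_duration

    def pulse_windows(self) -> list[tuple[float, float]]:
        """[(start, end), ...] of all influx windows in ms."""
        return [
            (k * self.period, k * self.period + self.pulse_duration)
            for k in range(self.n_pulses)
        ]

    def in_pulse(self, t: float) -> bool:
        """Whether time ``t`` (ms) lies inside an influx window."""
        if t < 0:
            return False
        k = math.floor(t / self.period)
        if k >= self.n_pulses:
            return False
        return (t - k * self.period) < self.pulse_duration

    def voltage_at(self, t: float) -> float:
        """Commanded membrane potential (mV) at time ``t`` (ms).

        Times before 0 sit at the test potential (the pre-step to the test
        level has already happened; the pre_potential is the holding level
        before that and never overlaps the recorded window).
        """
        return self.pulse_potential if self.in_pulse(t) else self.test_potential


def uniform_concentration_increment(geometry: CellGeometry, ions: float) -> float:
    """Well-mixed, unbuffered concentration rise (µM) from ``ions`` Ca²⁺
    ions distributed over the accessible volume."""
    if ions < 0:
        raise ValueError("ions must be >= 0")
    return ions / (IONS_PER_UM_UM3 * geometry.accessible_volume)


def ions_from_concentration(geometry: CellGeometry, conc_uM: float) -> float:
    """Inverse of :func:`uniform_concentration_increment`."""
    return conc_uM * IONS_PER_UM_UM3 * geometry.accessible_volume
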