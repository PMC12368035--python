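"""Shared fixtures: default study conditions and cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

import caclear as cc


@pytest.fixture(scope="session")
def geometry():
    """Default cell: 300 µm² surface, 30% accessible volume."""
    return cc.CellGeometry()


@pytest.fixture(scope="session")
def pipette_geometry():
    return cc.CellGeometry(pipette_contact_radius=1.0)


@pytest.fixture(scope="session")
def truth():
    return cc.default_truth()


@pytest.fixture(scope="session")
def protocol():
    return cc.InfluxProtocol()


@pytest.fixture(scope="session")
def v_grid():
    return np.arange(-80.0, 201.0, 10.0)


@pytest.fixture(scope="session")
def pulse_buffered(geometry, truth, protocol):
    """Single pulse, 10 mM EGTA, no pumps (buffer-limited clearance)."""
    return cc.run_pulse_experiment(
        geometry,
        cc.PumpParams(cycle_rate=0.0),
        cc.BufferParams(b_total=10000.0),
        protocol,
        truth.bk_kinetic,
    )


@pytest.fixture(scope="session")
def pulse_pumped():
    """Single pulse, low-buffer condition (modelled buffer-free), pumps at
    20,000 cycles/s — keyed by rate so tests can share runs."""
    cache: dict[float, cc.PulseResult] = {}
    geometry = cc.CellGeometry()
    truth = cc.default_truth()
    protocol = cc.InfluxProtocol()

    def run(rate: float) -> cc.PulseResult:
        if rate not in cache:
            cache[rate] = cc.run_pulse_experiment(
                geometry,
                cc.PumpParams(cycle_rate=rate),
                cc.BufferParams(b_total=0.0),
                protocol,
                truth.bk_kinetic,
            )
        return cache[rate]

    return run
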