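"""Shared fixtures: fixture materials, scaled-down geometries, responses,
and cached end-to-end pipeline runs reused across test modules."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import dectbench as db
from dectbench.experiments import Bench, BenchConfig

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def materials():
    return db.load_materials()


@pytest.fixture(scope="session")
def water(materials):
    return materials["water"]


@pytest.fixture(scope="session")
def geometry():
    """Half-scale geometry: fast but still quantitatively usable."""
    return db.FanBeamGeometry.scaled(360, 184)


@pytest.fixture(scope="session")
def geometry_tiny():
    """Quarter-scale geometry for smoke tests."""
    return db.FanBeamGeometry.scaled(180, 92)


@pytest.fixture(scope="session")
def bowtie(geometry):
    return db.bowtie_profile(geometry.fan_angles)


@pytest.fixture(scope="session")
def response_le(materials, bowtie):
    return db.build_energy_response(80.0, bowtie, label="LE",
                                    filter_material=materials["aluminum"])


@pytest.fixture(scope="session")
def response_he(materials, bowtie):
    return db.build_energy_response(120.0, bowtie, label="HE",
                                    filter_material=materials["aluminum"])


def mono_response(geometry, e0: float, label: str):
    """Single-energy response: one-hot weights at e0 on a small grid."""
    grid = db.EnergyGrid.from_range(e0 - 2.0, e0 + 2.0, 1.0)
    w = np.zeros((geometry.n_channels, len(grid)))
    w[:, 2] = 1.0
    return db.EnergyResponse(label=label, weights=w, grid=grid)


@pytest.fixture(scope="session")
def acr(materials):
    return db.make_acr_module_a(materials)


@pytest.fixture(scope="session")
def bench_small(materials):
    """Half-scale matched-model bench (no kernel mismatch)."""
    return Bench(BenchConfig(n_projections=360, n_channels=184,
                             model_mismatch=False))


@pytest.fixture(scope="session")
def acr_raw_small(bench_small, acr):
    """Noise-free LE/HE ACR scans with matched-model scatter."""
    return bench_small.simulate_pair(acr)


@pytest.fixture(scope="session")
def matched_densities_small(bench_small, acr_raw_small):
    """Data-based density images, matched-model scatter subtraction."""
    raw_le, raw_he = acr_raw_small
    f_w, f_c, report = bench_small.data_based_densities(
        raw_le, raw_he, scatter_mode="known")
    return f_w, f_c, report
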