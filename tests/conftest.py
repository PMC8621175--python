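"""Shared fixtures and builders for the test suite."""

import math

import numpy as np
import pytest

from polypack.cell import SimulationCell
from polypack.configuration import Configuration
from polypack.generate import generate_dilute_system
from polypack.topology import SpeciesTopology


def monomer_config(coords, lengths, **cell_kw):
    """Configuration of unbonded monomers at explicit coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    cell = SimulationCell(lengths, **cell_kw)
    topo = SpeciesTopology([], range(coords.shape[0]))
    return Configuration(coords, topo, cell)


def random_monomers(n, phi, seed, dim=3):
    """Dilute random non-overlapping monomer system at packing density phi."""
    if dim == 3:
        L = (n * math.pi / 6.0 / phi) ** (1.0 / 3.0)
    else:
        L = (n * math.pi / 4.0 / phi) ** 0.5
    cell = SimulationCell([L] * dim)
    return generate_dilute_system(0, 0, n, cell, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
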