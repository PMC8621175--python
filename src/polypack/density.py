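"""Packing-density measures for bulk, confined and filled systems.

Three measures, all dimensionless fractions of occupied volume:

* ``phi``       -- V_mon / V, with V the cell (or confined-region) volume and
  ``V_mon = (pi/6) N_at sigma^3`` the volume of the monomers themselves
  (``(pi/4) N_at sigma^2`` per disk in 2-D);
* ``phi_eff``   -- V_mon / (V - V_fill): the filler volume is removed from the
  denominator, since a large nanofiller can occupy orders of magnitude more
  volume than all the monomers together;
* ``phi_dep``   -- V_mon / V_dep where V_dep additionally strips the sigma/2
  depletion layer next to every wall and filler surface that monomer centers
  cannot enter:

  ``V_dep = prod_{i confined} (d_wall(i) - sigma) * prod_{j free} l_j
  - (pi/6)(d_sph + sigma)^3 N_sph - (pi/4)(d_cyl + sigma)^2 L_cyl N_cyl``.

In the bulk, filler-free limit the three coincide; otherwise
``phi_dep <= phi_eff <= phi`` (accessible volume only shrinks).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cell import (
    CylinderConfinement,
    SimulationCell,
    SphereConfinement,
    Walls,
    min_image_distance,
)
from .configuration import Configuration
from .errors import DegenerateGeometryError, InvalidCellError
from .fillers import CylinderFiller, SphereFiller, total_filler_volume

__all__ = [
    "monomer_volume",
    "packing_density",
    "effective_density",
    "depleted_density",
    "min_image_distance",
]


def monomer_volume(n_at: int, sigma: float = 1.0, dim: int = 3) -> float:
    """Total volume (3-D) or area (2-D) occupied by ``n_at`` monomers."""
    if dim == 2:
        return np.pi / 4.0 * n_at * sigma**2
    return np.pi / 6.0 * n_at * sigma**3


def _cell_of(config_or_cell) -> SimulationCell:
    if isinstance(config_or_cell, Configuration):
        return config_or_cell.cell
    return config_or_cell


def packing_density(config: Configuration) -> float:
    """Packing density phi = (pi/6) (N_at / V) sigma^3 (disks: pi/4 ... ^2)."""
    V = config.cell.volume
    if not np.isfinite(V) or V <= 0:
        raise InvalidCellError("cell volume must be positive")
    return monomer_volume(config.n_sites, config.sigma, config.dim) / V


def effective_density(config: Configuration, fillers: Sequence | None = None) -> float:
    """Effective packing density phi_eff = V_mon / (V - V_fill).

    ``fillers`` defaults to the configuration's own fillers.  Filler volumes
    are counted once (each filler lies inside the cell; cylinders span it
    exactly once along their axis).
    """
    cell = config.cell
    fillers = config.fillers if fillers is None else tuple(fillers)
    V = cell.volume
    V_fill = total_filler_volume(fillers, cell)
    V_acc = V - V_fill
    if V_acc <= 0:
        raise DegenerateGeometryError(
            f"fillers occupy the whole cell (V={V}, V_fill={V_fill})"
        )
    return monomer_volume(config.n_sites, config.sigma, config.dim) / V_acc


def depleted_density(config: Configuration, fillers: Sequence | None = None) -> float:
    """Depleted effective packing density phi_dep = V_mon / V_dep.

    Walls shrink their dimension by sigma; fillers are inflated by sigma on
    the diameter (cylinder lengths are cell-spanning hence not inflated).
    With cylindrical/spherical confinement the confining diameter is shrunk
    by sigma in the same way.
    """
    cell = config.cell
    sigma = config.sigma
    fillers = config.fillers if fillers is None else tuple(fillers)
    conf = cell.confinement

    if conf is None or isinstance(conf, Walls):
        factors = np.where(
            cell.confined_dims, cell.lengths - sigma, cell.lengths
        )
        if np.any(factors <= 0):
            raise DegenerateGeometryError("wall spacing does not exceed sigma")
        V_dep = float(np.prod(factors))
    elif isinstance(conf, CylinderConfinement):
        d = conf.diameter - sigma
        la = cell.lengths[conf.axis] - (sigma if conf.closed else 0.0)
        if d <= 0 or la <= 0:
            raise DegenerateGeometryError("cylinder narrower than sigma")
        V_dep = np.pi / 4.0 * d**2 * la
    elif isinstance(conf, SphereConfinement):
        d = conf.diameter - sigma
        if d <= 0:
            raise DegenerateGeometryError("sphere narrower than sigma")
        V_dep = (np.pi / 4.0 * d**2) if cell.dim == 2 else (np.pi / 6.0 * d**3)
    else:  # pragma: no cover
        raise InvalidCellError(f"unknown confinement {conf!r}")

    for f in fillers:
        if isinstance(f, SphereFiller):
            if cell.dim == 2:
                V_dep -= np.pi / 4.0 * (f.diameter + sigma) ** 2
            else:
                V_dep -= np.pi / 6.0 * (f.diameter + sigma) ** 3
        elif isinstance(f, CylinderFiller):
            V_dep -= np.pi / 4.0 * (f.diameter + sigma) ** 2 * f.length(cell)
        else:  # pragma: no cover
            raise InvalidCellError(f"unknown filler {f!r}")
    if V_dep <= 0:
        raise DegenerateGeometryError("depleted volume is not positive")
    return monomer_volume(config.n_sites, sigma, cell.dim) / V_dep
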