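"""Immobile nanofillers: spheres and cell-spanning cylinders.

Fillers are hard inclusions; monomer centers must stay at least ``sigma/2``
from a filler surface (the depletion layer).  Cylindrical fillers span the
whole cell along their axis and keep a fixed direction; spherical fillers
carry a ``mobile`` flag for completeness but are treated as immobile by the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import SimulationCell
from .errors import InvalidCellError


@dataclass(frozen=True)
class SphereFiller:
    """Impenetrable nanosphere of diameter ``diameter`` at ``center``."""

    center: tuple
    diameter: float
    mobile: bool = False

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidCellError("filler diameter must be positive")

    def volume(self, cell: SimulationCell) -> float:
        if cell.dim == 2:
            return float(np.pi / 4.0 * self.diameter**2)
        return float(np.pi / 6.0 * self.diameter**3)

    def surface_distance(self, coords: np.ndarray, cell: SimulationCell) -> np.ndarray:
        """Signed distance from points to the filler surface (negative = inside)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        d = cell.min_image_displacement(coords - np.asarray(self.center, dtype=float))
        return np.linalg.norm(d, axis=1) - self.diameter / 2.0


@dataclass(frozen=True)
class CylinderFiller:
    """Impenetrable nanocylinder spanning the whole cell along ``axis``.

    ``anchor`` fixes the axis position in the transverse dimensions (the
    coordinate along ``axis`` is ignored).  The length equals the cell
    length along the axis.
    """

    anchor: tuple
    diameter: float
    axis: int = 2
    mobile: bool = False

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidCellError("filler diameter must be positive")

    def length(self, cell: SimulationCell) -> float:
        return float(cell.lengths[self.axis])

    def volume(self, cell: SimulationCell) -> float:
        return float(np.pi / 4.0 * self.diameter**2 * self.length(cell))

    def surface_distance(self, coords: np.ndarray, cell: SimulationCell) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        trans = [k for k in range(cell.dim) if k != self.axis]
        anchor = np.asarray(self.anchor, dtype=float)
        d = coords[:, trans] - anchor[trans]
        for j, k in enumerate(trans):
            if cell.periodic[k]:
                l = cell.lengths[k]
                d[:, j] -= l * np.round(d[:, j] / l)
        return np.linalg.norm(d, axis=1) - self.diameter / 2.0


def total_filler_volume(fillers, cell: SimulationCell) -> float:
    """Sum of filler volumes V_fill = sum V_cyl + sum V_sph."""
    return float(sum(f.volume(cell) for f in fillers))
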