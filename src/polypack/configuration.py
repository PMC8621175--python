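"""System configuration: coordinates + topology + cell + fillers."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np

from .cell import SimulationCell
from .errors import InvalidCellError
from .topology import SpeciesTopology


class Configuration:
    """Site coordinates bound to a topology, a cell and optional fillers.

    Coordinates are continuous, in sigma units, wrapped into ``[0, l)`` on
    periodic dimensions at construction time.
    """

    def __init__(
        self,
        coords: np.ndarray,
        topology: SpeciesTopology,
        cell: SimulationCell,
        fillers: Sequence = (),
        sigma: float = 1.0,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != cell.dim:
            raise InvalidCellError(
                f"coordinates must be (N, {cell.dim}), got {coords.shape}"
            )
        if coords.shape[0] != topology.n_sites:
            raise InvalidCellError(
                "coordinate count does not match topology site count"
            )
        self.coords = cell.wrap(coords)
        self.topology = topology
        self.cell = cell
        self.fillers: Tuple = tuple(fillers)
        self.sigma = float(sigma)

    # ------------------------------------------------------------------ #
    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.cell.dim

    def species(self) -> np.ndarray:
        _, _, species = self.topology.site_tables()
        return species

    def displacement(self, i: int, j: int) -> np.ndarray:
        """Minimum-image displacement from site i to site j."""
        return self.cell.min_image_displacement(self.coords[j] - self.coords[i])

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.displacement(i, j)))

    def copy(self) -> "Configuration":
        return Configuration(
            self.coords.copy(),
            self.topology.copy(),
            self.cell,
            self.fillers,
            self.sigma,
        )

    def clearance_ok(self, coords: np.ndarray | None = None) -> bool:
        """True if all centers respect the sigma/2 wall and filler layer."""
        c = self.coords if coords is None else np.atleast_2d(coords)
        half = self.sigma / 2.0
        tol = 1e-12
        if self.cell.d_conf and np.any(self.cell.surface_clearance(c) < half - tol):
            return False
        for f in self.fillers:
            if np.any(f.surface_distance(c, self.cell) < half - tol):
                return False
        return True
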