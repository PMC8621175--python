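"""Orthogonal simulation cells with periodic boundaries and hard confinement.

Reduced units are used throughout the package: the monomer collision diameter
``sigma`` is the unit of length and ``k_B T`` the unit of energy.  Cells are
orthogonal with the origin at a corner; coordinates on periodic dimensions are
wrapped into ``[0, l)``, confined dimensions are never wrapped.

Confinement is one of

* :class:`Walls` -- impenetrable flat walls closing one or more dimensions,
  with inter-wall distance ``d_wall(i)`` equal to the cell length on that
  dimension;
* :class:`CylinderConfinement` -- a cylinder spanning the cell along one axis,
  with open (periodic) or closed ends;
* :class:`SphereConfinement` -- full confinement inside a sphere.

Monomer *centers* may not come closer than ``sigma/2`` to any confining
surface; that check lives in :func:`SimulationCell.surface_clearance` and is
consumed by the overlap tests of :mod:`polypack.interactions`.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import InvalidCellError


@dataclass(frozen=True)
class Walls:
    """Flat parallel walls on each dimension in ``dims``."""

    dims: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.dims)) != len(self.dims):
            raise InvalidCellError("duplicate confined dimensions in Walls")


@dataclass(frozen=True)
class CylinderConfinement:
    """Cylinder spanning the whole cell along dimension ``axis``.

    The cylinder axis passes through the cell center of the transverse
    dimensions.  ``closed`` ends add flat walls on the axis dimension,
    otherwise the axis dimension stays periodic.
    """

    diameter: float
    axis: int = 2
    closed: bool = False

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidCellError("cylinder diameter must be positive")


@dataclass(frozen=True)
class SphereConfinement:
    """Full confinement inside a sphere centered in the cell."""

    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidCellError("sphere diameter must be positive")


Confinement = Union[Walls, CylinderConfinement, SphereConfinement]


@dataclass(frozen=True)
class SimulationCell:
    """Orthogonal cell in 2 or 3 dimensions with optional confinement.

    Parameters
    ----------
    lengths : sequence of float
        Edge lengths ``l_1..l_dim`` in sigma units; all positive.
    confinement : Walls, CylinderConfinement, SphereConfinement or None
        Hard confinement; the affected dimensions are automatically
        non-periodic.
    periodic : sequence of bool, optional
        Per-dimension periodicity.  Defaults to periodic everywhere except
        on confined dimensions.  Supplying ``periodic=True`` on a confined
        dimension is an error.
    """

    lengths: np.ndarray
    confinement: Optional[Confinement] = None
    periodic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.ndim != 1 or lengths.size not in (2, 3):
            raise InvalidCellError("cell must be 2- or 3-dimensional")
        if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
            raise InvalidCellError("all cell lengths must be positive finite")
        object.__setattr__(self, "lengths", lengths)

        confined = np.zeros(lengths.size, dtype=bool)
        conf = self.confinement
        if isinstance(conf, Walls):
            for d in conf.dims:
                if not 0 <= d < lengths.size:
                    raise InvalidCellError(f"wall dimension {d} out of range")
                confined[d] = True
        elif isinstance(conf, CylinderConfinement):
            if lengths.size != 3:
                raise InvalidCellError("cylindrical confinement requires 3-D")
            if not 0 <= conf.axis < 3:
                raise InvalidCellError("cylinder axis out of range")
            confined[:] = True
            confined[conf.axis] = conf.closed
            for d in range(3):
                if d != conf.axis and lengths[d] < conf.diameter:
                    raise InvalidCellError(
                        "cell must enclose the confining cylinder"
                    )
        elif isinstance(conf, SphereConfinement):
            confined[:] = True
            if np.any(lengths < conf.diameter):
                raise InvalidCellError("cell must enclose the confining sphere")
        elif conf is not None:
            raise InvalidCellError(f"unknown confinement {conf!r}")

        if self.periodic is None:
            periodic = ~confined
        else:
            periodic = np.asarray(self.periodic, dtype=bool)
            if periodic.shape != lengths.shape:
                raise InvalidCellError("periodic flags must match dimensions")
            if np.any(periodic & confined):
                raise InvalidCellError("confined dimensions cannot be periodic")
        object.__setattr__(self, "periodic", periodic)
        object.__setattr__(self, "_confined", confined)
        object.__setattr__(self, "_per_idx", tuple(np.flatnonzero(periodic)))
        object.__setattr__(self, "_len_list", tuple(float(v) for v in lengths))

    # ------------------------------------------------------------------ #
    @property
    def dim(self) -> int:
        return self.lengths.size

    @property
    def confined_dims(self) -> np.ndarray:
        """Boolean mask of confined dimensions."""
        return self._confined.copy()

    @property
    def d_conf(self) -> int:
        """Number of confined dimensions (0 = bulk ... dim = full)."""
        return int(self._confined.sum())

    @property
    def center(self) -> np.ndarray:
        return self.lengths / 2.0

    @property
    def volume(self) -> float:
        """Volume (3-D) or area (2-D) of the accessible simulation region.

        For walls / bulk this is the product of the cell lengths; for
        cylindrical and spherical confinement it is the volume of the
        confining body itself, which is what the packing density of a
        confined system is measured against.
        """
        conf = self.confinement
        if isinstance(conf, CylinderConfinement):
            return float(np.pi / 4.0 * conf.diameter**2 * self.lengths[conf.axis])
        if isinstance(conf, SphereConfinement):
            if self.dim == 2:
                return float(np.pi / 4.0 * conf.diameter**2)
            return float(np.pi / 6.0 * conf.diameter**3)
        return float(np.prod(self.lengths))

    @property
    def wall_distances(self) -> np.ndarray:
        """Characteristic inter-surface distance per dimension.

        Cell length on wall-confined and bulk dimensions, the diameter on
        dimensions closed by a cylinder or sphere.
        """
        d = self.lengths.copy()
        conf = self.confinement
        if isinstance(conf, CylinderConfinement):
            for k in range(3):
                if k != conf.axis:
                    d[k] = conf.diameter
        elif isinstance(conf, SphereConfinement):
            d[:] = conf.diameter
        return d

    @property
    def aspect_ratio(self) -> float:
        """Cell aspect ratio zeta = max inter-wall distance / min."""
        d = self.wall_distances
        return float(d.max() / d.min())

    # ------------------------------------------------------------------ #
    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into ``[0, l)`` on periodic dimensions."""
        out = np.array(coords, dtype=float, copy=True)
        per = self.periodic
        out[..., per] = np.mod(out[..., per], self.lengths[per])
        return out

    def min_image_displacement(self, d: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        out = np.array(d, dtype=float, copy=True)
        if out.ndim == 1:
            for k in self._per_idx:
                l = self._len_list[k]
                v = out[k] / l
                out[k] = l * (v - math.floor(v + 0.5))
            return out
        for k in self._per_idx:
            l = self._len_list[k]
            out[..., k] -= l * np.round(out[..., k] / l)
        return out

    def surface_clearance(self, coords: np.ndarray) -> np.ndarray:
        """Distance from each point to the nearest confining surface.

        Returns ``+inf`` for bulk cells.  Negative values mean the point is
        outside the confined region.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        out = np.full(coords.shape[0], np.inf)
        conf = self.confinement
        if isinstance(conf, Walls):
            for d in conf.dims:
                x = coords[:, d]
                out = np.minimum(out, np.minimum(x, self.lengths[d] - x))
        elif isinstance(conf, CylinderConfinement):
            trans = [k for k in range(3) if k != conf.axis]
            r = np.linalg.norm(coords[:, trans] - self.center[trans], axis=1)
            out = np.minimum(out, conf.diameter / 2.0 - r)
            if conf.closed:
                x = coords[:, conf.axis]
                out = np.minimum(
                    out, np.minimum(x, self.lengths[conf.axis] - x)
                )
        elif isinstance(conf, SphereConfinement):
            r = np.linalg.norm(coords - self.center, axis=1)
            out = np.minimum(out, conf.diameter / 2.0 - r)
        return out

    def scaled(self, factors: Sequence[float]) -> "SimulationCell":
        """Return a copy with lengths multiplied by ``factors`` (per dim)."""
        return SimulationCell(
            self.lengths * np.asarray(factors, dtype=float),
            confinement=self.confinement,
            periodic=self.periodic,
        )


def min_image_distance(p, q, cell: SimulationCell) -> float:
    """Minimum-image Euclidean distance between two points.

    Periodicity is honored only on the cell's periodic dimensions.
    """
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return float(np.linalg.norm(cell.min_image_displacement(d)))
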