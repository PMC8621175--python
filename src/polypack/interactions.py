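"""Bonded and non-bonded interactions, cell lists, overlap and energy sums.

Supported non-bonded pair potentials (energies in k_B*T, lengths in sigma):

* ``HS``  hard spheres: infinite below the collision diameter sigma, zero
  beyond;
* ``SW``  square well: hard core plus a constant well ``-eps_sw`` on
  ``[sigma, sigma2)``;
* ``SS``  square shoulder: same geometry with ``+eps_sw``;
* ``LJ``  Lennard-Jones ``4 eps_lj [(sigma_lj/r)^12 - (sigma_lj/r)^6]``,
  truncated and shifted to zero at the cut-off.

Chains carry a bond-length constraint (``[bond_lower, sigma + dl]``, tangency
``dl = 0`` supported), a harmonic bending potential ``k_theta (theta -
theta0)^2`` acting on the supplement of the bond angle (``theta0 = 0`` is a
fully extended triplet) and an optional torsion potential hook (off by
default; torsions then fluctuate freely).

Hard-core violations are reported as an infinite-energy sentinel
(``math.inf``), never as exceptions, so Metropolis acceptance can treat them
uniformly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional

import numpy as np

from .configuration import Configuration

_TOL = 1e-9  # slack for tangent bonds / exact-contact pairs


@dataclass(frozen=True)
class BendingSpec:
    """Harmonic bending stiffness: U = k_theta * (theta - theta0)^2.

    ``theta`` is the supplement of the internal bond angle, in radians;
    ``k_theta`` is in k_B*T per rad^2.  ``k_theta = 0`` gives freely jointed
    chains.
    """

    k_theta: float = 0.0
    theta0: float = 0.0

    def __post_init__(self):
        if self.k_theta < 0:
            raise ValueError("bending constant must be non-negative")


@dataclass(frozen=True)
class InteractionSpec:
    """Full interaction model of a system."""

    mode: str = "HS"                  # HS | SW | SS | LJ
    sigma: float = 1.0                # collision diameter
    sigma2: float = 1.5               # SW/SS outer range
    eps_sw: float = 1.0               # SW well depth / SS shoulder height
    eps_lj: float = 1.0
    sigma_lj: float = 1.0
    lj_cutoff: Optional[float] = None  # default 2.5 sigma_lj
    lj_shift: bool = True
    dl: float = 0.0                   # bond gap: bonds in [bond_lower, sigma+dl]
    bond_lower: Optional[float] = None  # default sigma (no fused spheres)
    bending: BendingSpec = field(default_factory=BendingSpec)
    torsion: Optional[Callable[[float], float]] = None
    exclude_13: bool = False          # exclude 1-3 pairs from non-bonded sums

    def __post_init__(self):
        if self.mode not in ("HS", "SW", "SS", "LJ"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mode in ("SW", "SS") and self.sigma2 <= self.sigma:
            raise ValueError("sigma2 must exceed sigma for SW/SS")
        if self.dl < 0:
            raise ValueError("bond gap dl must be non-negative")

    @property
    def cutoff(self) -> float:
        """Outer interaction range (neighbor-search radius)."""
        if self.mode == "HS":
            return self.sigma
        if self.mode in ("SW", "SS"):
            return self.sigma2
        return self.lj_cutoff if self.lj_cutoff is not None else 2.5 * self.sigma_lj

    @property
    def hard_core(self) -> bool:
        return self.mode in ("HS", "SW", "SS")

    @property
    def bond_min(self) -> float:
        return self.sigma if self.bond_lower is None else self.bond_lower

    @property
    def bond_max(self) -> float:
        return self.sigma + self.dl


# ---------------------------------------------------------------------- #
# elementary energies
# ---------------------------------------------------------------------- #
def pair_energy(r: float, spec: InteractionSpec) -> float:
    """Non-bonded pair energy at center distance ``r`` (k_B*T)."""
    if spec.mode == "HS":
        return math.inf if r < spec.sigma - _TOL else 0.0
    if spec.mode in ("SW", "SS"):
        if r < spec.sigma - _TOL:
            return math.inf
        if r < spec.sigma2:
            return -spec.eps_sw if spec.mode == "SW" else spec.eps_sw
        return 0.0
    # LJ, truncated (and by default shifted to zero) at the cut-off
    rc = spec.cutoff
    if r >= rc:
        return 0.0
    u = _lj(r, spec)
    if spec.lj_shift:
        u -= _lj(rc, spec)
    return u


def _lj(r: float, spec: InteractionSpec) -> float:
    x6 = (spec.sigma_lj / r) ** 6
    return 4.0 * spec.eps_lj * (x6 * x6 - x6)


def bending_energy(theta: float, spec: InteractionSpec) -> float:
    """Bending energy k_theta (theta - theta0)^2 of a supplement angle."""
    b = spec.bending
    if b.k_theta == 0.0:
        return 0.0
    return b.k_theta * (theta - b.theta0) ** 2


def bond_energy(r: float, spec: InteractionSpec) -> float:
    """0 inside the allowed bond window, infinity outside."""
    if spec.bond_min - _TOL <= r <= spec.bond_max + _TOL:
        return 0.0
    return math.inf


def bending_angle(r_prev: np.ndarray, r_mid: np.ndarray, r_next: np.ndarray,
                  config: Configuration) -> float:
    """Supplement bending angle of a bonded triplet, in radians.

    0 corresponds to a fully extended (collinear) triplet.
    """
    b1 = config.cell.min_image_displacement(r_mid - r_prev)
    b2 = config.cell.min_image_displacement(r_next - r_mid)
    c = float(np.dot(b1, b2) / (np.linalg.norm(b1) * np.linalg.norm(b2)))
    return math.acos(max(-1.0, min(1.0, c)))


def torsion_angle(p0, p1, p2, p3, config: Configuration) -> float:
    """Dihedral angle of a bonded quadruplet, in radians in (-pi, pi]."""
    mic = config.cell.min_image_displacement
    b1, b2, b3 = mic(p1 - p0), mic(p2 - p1), mic(p3 - p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.atan2(y, x)


# ---------------------------------------------------------------------- #
# cell lists
# ---------------------------------------------------------------------- #
class CellListGrid:
    """Uniform binning grid with bin edge >= interaction range.

    Neighbor queries over the 3^dim stencil around a bin are guaranteed to
    find every pair within ``range_``.  Works for periodic and confined
    dimensions (the stencil is clipped on non-periodic dimensions).
    """

    def __init__(self, config_or_cell, range_: float, coords=None):
        if isinstance(config_or_cell, Configuration):
            cell = config_or_cell.cell
            if coords is None:
                coords = config_or_cell.coords
        else:
            cell = config_or_cell
        self.range = float(range_)
        self.cell = cell
        self.nbins = np.maximum(1, (cell.lengths / self.range).astype(int))
        self.widths = cell.lengths / self.nbins
        self._bins: dict[tuple, set] = {}
        self._site_bin: dict[int, tuple] = {}
        self._stencil: dict[tuple, list] = {}
        if coords is not None:
            for i, x in enumerate(coords):
                self.insert(i, x)

    def _bin_of(self, x: np.ndarray) -> tuple:
        idx = np.floor(np.asarray(x) / self.widths).astype(int)
        idx = np.minimum(np.maximum(idx, 0), self.nbins - 1)
        return tuple(idx)

    def insert(self, i: int, x: np.ndarray) -> None:
        b = self._bin_of(x)
        self._bins.setdefault(b, set()).add(i)
        self._site_bin[i] = b

    def remove(self, i: int) -> None:
        b = self._site_bin.pop(i)
        self._bins[b].discard(i)

    def move(self, i: int, x_new: np.ndarray) -> None:
        b = self._bin_of(x_new)
        old = self._site_bin[i]
        if b != old:
            self._bins[old].discard(i)
            self._bins.setdefault(b, set()).add(i)
            self._site_bin[i] = b

    def candidates(self, x: np.ndarray):
        """Site indices in the 3^dim bin stencil around position ``x``."""
        b = self._bin_of(x)
        stencil = self._stencil.get(b)
        if stencil is None:
            per = self.cell.periodic
            axes = []
            for k in range(len(b)):
                n = int(self.nbins[k])
                vals = {(b[k] + d) % n if per[k] else b[k] + d
                        for d in (-1, 0, 1)}
                axes.append([v for v in vals if 0 <= v < n])
            stencil = [tuple(bb) for bb in product(*axes)]
            self._stencil[b] = stencil
        out = []
        for bb in stencil:
            s = self._bins.get(bb)
            if s:
                out.extend(s)
        return out


class NeighborGrids:
    """Overlap-range and cut-off-range grids for a configuration.

    For HS only the overlap grid exists; SW/SS/LJ also carry a wider
    cut-off grid used for energy sums.
    """

    def __init__(self, config: Configuration, spec: InteractionSpec):
        self.spec = spec
        rng = max(spec.cutoff, spec.bond_max)
        self.overlap = CellListGrid(config, max(spec.sigma, spec.bond_max))
        if rng > self.overlap.range:
            self.energy = CellListGrid(config, rng)
        else:
            self.energy = self.overlap

    def move(self, i: int, x_new: np.ndarray) -> None:
        self.overlap.move(i, x_new)
        if self.energy is not self.overlap:
            self.energy.move(i, x_new)

    def insert(self, i: int, x: np.ndarray) -> None:
        self.overlap.insert(i, x)
        if self.energy is not self.overlap:
            self.energy.insert(i, x)

    def remove(self, i: int) -> None:
        self.overlap.remove(i)
        if self.energy is not self.overlap:
            self.energy.remove(i)


# ---------------------------------------------------------------------- #
# energy / overlap sums
# ---------------------------------------------------------------------- #
def _excluded_pairs(config: Configuration, i: int, spec: InteractionSpec) -> set:
    """Sites excluded from non-bonded interaction with ``i`` (1-2, opt. 1-3)."""
    topo = config.topology
    out = set(topo.bonded_neighbors(i))
    if spec.exclude_13:
        for j in list(out):
            out.update(topo.bonded_neighbors(j))
        out.discard(i)
    return out


def nonbonded_site_energy(
    config: Configuration,
    i: int,
    spec: InteractionSpec,
    grids: Optional[NeighborGrids] = None,
    pos: Optional[np.ndarray] = None,
) -> float:
    """Non-bonded energy of site ``i`` (optionally at trial position ``pos``)."""
    x = config.coords[i] if pos is None else np.asarray(pos, dtype=float)
    if grids is None:
        cand = range(config.n_sites)
    else:
        cand = grids.energy.candidates(x)
    excl = _excluded_pairs(config, i, spec)
    rc = spec.cutoff
    e = 0.0
    for j in cand:
        if j == i or j in excl:
            continue
        d = config.cell.min_image_displacement(config.coords[j] - x)
        r = float(np.linalg.norm(d))
        if r < rc + _TOL:
            e += pair_energy(r, spec)
            if e == math.inf:
                return math.inf
    return e


def bonded_site_energy(config: Configuration, i: int, spec: InteractionSpec) -> float:
    """Bond-window, bending and torsion terms that involve site ``i``."""
    topo = config.topology
    cid, pos_in, _ = topo.site_tables()
    if cid[i] < 0:
        return 0.0
    chain = topo.chains[cid[i]]
    p = pos_in[i]
    e = 0.0
    coords = config.coords
    for a in (p - 1, p):
        if 0 <= a < len(chain) - 1:
            r = config.distance(chain[a], chain[a + 1])
            e += bond_energy(r, spec)
            if e == math.inf:
                return math.inf
    if spec.bending.k_theta > 0:
        for a in (p - 2, p - 1, p):
            if 0 <= a <= len(chain) - 3:
                th = bending_angle(
                    coords[chain[a]], coords[chain[a + 1]], coords[chain[a + 2]], config
                )
                e += bending_energy(th, spec)
    if spec.torsion is not None and len(chain) >= 4:
        for a in (p - 3, p - 2, p - 1, p):
            if 0 <= a <= len(chain) - 4:
                phi = torsion_angle(
                    *(coords[chain[a + k]] for k in range(4)), config
                )
                e += spec.torsion(phi)
    return e


def site_energy(
    config: Configuration,
    i: int,
    spec: InteractionSpec,
    grids: Optional[NeighborGrids] = None,
) -> float:
    """Total energy terms involving site ``i`` (non-bonded + bonded)."""
    e = nonbonded_site_energy(config, i, spec, grids)
    if e == math.inf:
        return math.inf
    return e + bonded_site_energy(config, i, spec)


def total_energy(
    config: Configuration,
    spec: InteractionSpec,
    grids: Optional[NeighborGrids] = None,
) -> float:
    """Total system energy: half-sum-consistent non-bonded + all bonded terms."""
    e = 0.0
    for i in range(config.n_sites):
        en = nonbonded_site_energy(config, i, spec, grids)
        if en == math.inf:
            return math.inf
        e += en
    e *= 0.5
    topo = config.topology
    coords = config.coords
    for chain in topo.chains:
        for a, b in zip(chain[:-1], chain[1:]):
            e += bond_energy(config.distance(a, b), spec)
            if e == math.inf:
                return math.inf
        if spec.bending.k_theta > 0:
            for a in range(len(chain) - 2):
                th = bending_angle(
                    coords[chain[a]], coords[chain[a + 1]], coords[chain[a + 2]], config
                )
                e += bending_energy(th, spec)
        if spec.torsion is not None:
            for a in range(len(chain) - 3):
                phi = torsion_angle(
                    *(coords[chain[a + k]] for k in range(4)), config
                )
                e += spec.torsion(phi)
    return e


def has_overlap(
    config: Configuration,
    i: Optional[int] = None,
    spec: Optional[InteractionSpec] = None,
    grids: Optional[NeighborGrids] = None,
    pos: Optional[np.ndarray] = None,
) -> bool:
    """Hard-core / wall / filler violation test.

    True iff any non-bonded center pair is closer than sigma (tangency at
    exactly sigma is allowed), any bonded pair leaves its allowed window,
    or any center violates the sigma/2 clearance from walls and fillers
    (which also covers sites outside a closed confinement).  With ``i``
    given, only terms involving site ``i`` are tested (at trial position
    ``pos`` if supplied).
    """
    spec = spec if spec is not None else InteractionSpec()
    sigma = spec.sigma
    sites = range(config.n_sites) if i is None else [i]
    for s in sites:
        x = config.coords[s] if (pos is None or s != i) else np.asarray(pos)
        if not config.clearance_ok(x):
            return True
        excl = _excluded_pairs(config, s, spec)
        cand = (
            grids.overlap.candidates(x)
            if grids is not None
            else range(config.n_sites)
        )
        for j in cand:
            if j == s or (i is None and j < s):
                continue
            d = config.cell.min_image_displacement(config.coords[j] - x)
            r = float(np.linalg.norm(d))
            if j in excl:
                if r < spec.bond_min - _TOL or r > spec.bond_max + _TOL:
                    return True
            elif spec.hard_core and r < sigma - _TOL:
                return True
    return False
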