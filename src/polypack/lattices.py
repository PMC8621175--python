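"""Ideal and perturbed reference-lattice generators.

These fixtures back the descriptor validation: every reference crystal of
the descriptor catalog has a generator here that produces either a periodic
supercell (FCC, HCP, BCC, HEX, TRI, SQU, HON) or, for the local fivefold
symmetries that are not space-filling (FIV, PEN), a finite central-site
cluster in an open cell.

``spacing`` is the nearest-neighbor distance (sigma units); optional
Gaussian jitter of amplitude ``noise`` emulates thermal disorder.
"""

from __future__ import annotations

import numpy as np

from .cell import SimulationCell
from .configuration import Configuration
from .errors import ConfigError, GenerationError
from .topology import SpeciesTopology

SQ3 = np.sqrt(3.0)


def _supercell(cell_lengths, basis, repeats, spacing):
    reps = np.asarray(repeats, dtype=int)
    basis = np.asarray(basis, dtype=float)
    dim = basis.shape[1]
    shifts = np.stack(
        np.meshgrid(*[np.arange(r) for r in reps], indexing="ij"), axis=-1
    ).reshape(-1, dim)
    pts = (shifts[:, None, :] * np.asarray(cell_lengths)) + basis[None, :, :]
    lengths = np.asarray(cell_lengths) * reps
    return pts.reshape(-1, dim) * 1.0, lengths


_3D = ("FCC", "HCP", "BCC", "HEX", "FIV")
_2D = ("TRI", "SQU", "HON", "PEN")


def generate_ideal_lattice(
    crystal: str,
    repeats=4,
    spacing: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> Configuration:
    """Build an ideal (optionally jittered) reference-crystal configuration.

    Parameters
    ----------
    crystal : str
        One of FCC, HCP, BCC, HEX, FIV (3-D) or TRI, SQU, HON, PEN (2-D).
    repeats : int or tuple of int
        Supercell repeats per dimension (ignored for the finite FIV/PEN
        clusters).
    spacing : float
        Nearest-neighbor distance.
    noise : float
        Standard deviation of Gaussian positional jitter, sigma units.
    seed : int
        Seed for the jitter RNG.

    Raises
    ------
    ConfigError
        Unknown crystal name.
    GenerationError
        Supercell too small for a periodicity-consistent Voronoi
        tessellation.
    """
    name = crystal.upper()
    if name not in _3D + _2D:
        raise ConfigError(f"unknown reference crystal {crystal!r}")
    a = spacing
    dim = 3 if name in _3D else 2
    if np.isscalar(repeats):
        repeats = (int(repeats),) * dim

    if name == "FCC":
        c = a * np.sqrt(2.0)
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]) * c
        pts, lengths = _supercell([c] * 3, basis, repeats, a)
    elif name == "BCC":
        c = 2.0 * a / SQ3
        basis = np.array([[0, 0, 0], [0.5, 0.5, 0.5]]) * c
        pts, lengths = _supercell([c] * 3, basis, repeats, a)
    elif name == "HCP":
        cc = a * np.sqrt(8.0 / 3.0)
        cl = [a, SQ3 * a, cc]
        basis = np.array(
            [
                [0.0, 0.0, 0.0],
                [0.5 * a, 0.5 * SQ3 * a, 0.0],
                [0.5 * a, SQ3 * a / 6.0, 0.5 * cc],
                [0.0, 2.0 * SQ3 * a / 3.0, 0.5 * cc],
            ]
        )
        pts, lengths = _supercell(cl, basis, repeats, a)
    elif name == "HEX":
        # simple hexagonal with c = a: 6 in-plane + 2 axial neighbors
        cl = [a, SQ3 * a, a]
        basis = np.array([[0, 0, 0], [0.5 * a, 0.5 * SQ3 * a, 0]])
        pts, lengths = _supercell(cl, basis, repeats, a)
    elif name == "TRI":
        cl = [a, SQ3 * a]
        basis = np.array([[0, 0], [0.5 * a, 0.5 * SQ3 * a]])
        pts, lengths = _supercell(cl, basis, repeats, a)
    elif name == "SQU":
        pts, lengths = _supercell([a, a], np.array([[0.0, 0.0]]), repeats, a)
    elif name == "HON":
        cl = [3.0 * a, SQ3 * a]
        basis = np.array(
            [[0, 0], [a, 0], [1.5 * a, 0.5 * SQ3 * a], [2.5 * a, 0.5 * SQ3 * a]]
        )
        pts, lengths = _supercell(cl, basis, repeats, a)
    elif name in ("FIV", "PEN"):
        pts, lengths = _fivefold_cluster(name, a)
    else:  # pragma: no cover
        raise ConfigError(crystal)

    rng = np.random.default_rng(seed)
    if noise > 0:
        pts = pts + rng.normal(scale=noise, size=pts.shape)

    if name in ("FIV", "PEN"):
        cell = SimulationCell(lengths, periodic=[False] * dim)
    else:
        if np.any(lengths < 2.5 * a):
            raise GenerationError(
                "supercell too small for a periodicity-consistent Voronoi "
                "tessellation; increase repeats"
            )
        cell = SimulationCell(lengths)
    topo = SpeciesTopology([], range(len(pts)))
    return Configuration(pts, topo, cell)


def _fivefold_cluster(name: str, a: float):
    """Finite cluster exhibiting fivefold local symmetry around site 0."""
    if name == "PEN":
        ang = 2.0 * np.pi * np.arange(5) / 5.0
        shell = a * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        pts = np.vstack([[0.0, 0.0], shell])
        lengths = np.array([8.0 * a, 8.0 * a])
        return pts + lengths / 2.0, lengths
    # FIV: icosahedral 12-shell; circumradius r such that edge = a gives a
    # slightly larger center distance -- scale so *center* distance is a.
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = []
    for s1 in (-1.0, 1.0):
        for s2 in (-1.0, 1.0):
            verts += [
                [0.0, s1, s2 * phi],
                [s1, s2 * phi, 0.0],
                [s2 * phi, 0.0, s1],
            ]
    verts = np.array(verts)
    verts *= a / np.linalg.norm(verts[0])
    pts = np.vstack([[0.0, 0.0, 0.0], verts])
    lengths = np.array([8.0 * a] * 3)
    return pts + lengths / 2.0, lengths
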