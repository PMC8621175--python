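"""Reference-crystal catalog: coordination numbers and symmetry elements.

Each reference crystal is identified by a small set of characteristic
symmetry elements of its point group, expressed in a canonical frame as
generator matrices whose non-identity powers are the operations applied to
the neighbor shell.  A roto-inversion axis n-bar combines rotation by
2*pi/n with inversion through the site.

Default element sets (all overridable by constructing a custom catalog):

=====  =======  ========================================================
name   N_coord  elements (canonical frame)
=====  =======  ========================================================
FCC    12       three fourfold roto-inversion axes along x, y, z
HCP    12       one sixfold roto-inversion axis along z
BCC    8        four threefold roto-inversion axes along the cube
                diagonals, plus the inversion center
HEX    8        one sixfold rotation axis along z
FIV    12       one fivefold rotation axis along z (icosahedral shell)
TRI    6        sixfold rotation (2-D)
SQU    4        fourfold rotation (2-D)
HON    3        threefold rotation (2-D)
PEN    5        fivefold rotation (2-D)
=====  =======  ========================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ..errors import ConfigError


def _axis_rotation(axis, angle: float) -> np.ndarray:
    """3x3 rotation about ``axis`` by ``angle`` (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array(
        [[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]]
    )
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def _rot2d(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _generator_ops(axis, n: int, rotoinv: bool, powers=None) -> list[np.ndarray]:
    """Powers of an n-fold (roto-inversion) axis generator.

    By default all non-identity powers are produced; ``powers`` selects a
    subset (used to keep redundant operations out of large element sets).
    """
    g = _axis_rotation(axis, 2.0 * np.pi / n)
    if rotoinv:
        g = -g
    order = n if (n % 2 == 0 or not rotoinv) else 2 * n
    if powers is None:
        powers = range(1, order)
    return [np.linalg.matrix_power(g, int(p)) for p in powers]


@dataclass(frozen=True)
class CCEReferenceCrystal:
    """A reference crystal: name, dimensionality, coordination, operations.

    ``ops`` is an ``(n_ops, dim, dim)`` stack of symmetry operations in the
    canonical frame; during the norm evaluation they are conjugated by the
    scanned orientation.  ``elem_id`` groups operations by the symmetry
    element they belong to: the norm of a shell at a given orientation is
    the *worst* (largest) per-element RMS mismatch, so a crystal is matched
    only when every characteristic element maps the shell onto itself.
    ``multi_axis`` marks element sets whose overall orientation needs a
    third Euler angle (more than one distinct axis).
    """

    name: str
    dim: int
    n_coord: int
    ops: np.ndarray
    elem_id: np.ndarray
    multi_axis: bool
    gamma_period: float = 0.0  # scan range of the third Euler angle (rad)

    def __post_init__(self):
        if self.ops.shape[0] == 0:
            raise ConfigError(f"{self.name}: element list may not be empty")


def _crystal_3d(name, n_coord, elements, multi_axis, gamma_period=0.0):
    ops = []
    elem_id = []
    for k, element in enumerate(elements):
        axis, n, rotoinv = element[:3]
        powers = element[3] if len(element) > 3 else None
        if n == 1:  # bare inversion center
            new = [-np.eye(3)]
        else:
            new = _generator_ops(axis, n, rotoinv, powers)
        ops.extend(new)
        elem_id.extend([k] * len(new))
    return CCEReferenceCrystal(
        name, 3, n_coord, np.array(ops), np.array(elem_id, dtype=np.int64),
        multi_axis, gamma_period,
    )


def _crystal_2d(name, n_coord, n_fold):
    ops = [_rot2d(2.0 * np.pi * k / n_fold) for k in range(1, n_fold)]
    elem_id = np.zeros(len(ops), dtype=np.int64)
    return CCEReferenceCrystal(name, 2, n_coord, np.array(ops), elem_id, False)


_DIAG = [(1, 1, 1), (1, 1, -1), (1, -1, 1), (-1, 1, 1)]

DEFAULT_CATALOG: dict[str, CCEReferenceCrystal] = {
    c.name: c
    for c in [
        _crystal_3d(
            "FCC",
            12,
            [((1, 0, 0), 4, True), ((0, 1, 0), 4, True), ((0, 0, 1), 4, True)],
            multi_axis=True,
            gamma_period=np.pi / 2,
        ),
        _crystal_3d("HCP", 12, [((0, 0, 1), 6, True)], multi_axis=False),
        _crystal_3d(
            "BCC",
            8,
            [(d, 3, True) for d in _DIAG] + [(None, 1, False)],
            multi_axis=True,
            gamma_period=np.pi / 2,
        ),
        _crystal_3d("HEX", 8, [((0, 0, 1), 6, False)], multi_axis=False),
        _crystal_3d("FIV", 12, [((0, 0, 1), 5, False)], multi_axis=False),
        _crystal_2d("TRI", 6, 6),
        _crystal_2d("SQU", 4, 4),
        _crystal_2d("HON", 3, 3),
        _crystal_2d("PEN", 5, 5),
    ]
}

NAMES_3D = ("FCC", "HCP", "BCC", "HEX", "FIV")
NAMES_2D = ("TRI", "SQU", "HON", "PEN")


def get_catalog(dim: int, names=None) -> list[CCEReferenceCrystal]:
    """Catalog entries of a given dimensionality, optionally restricted."""
    if names is None:
        names = NAMES_3D if dim == 3 else NAMES_2D
    out = []
    for n in names:
        key = n.upper()
        if key not in DEFAULT_CATALOG:
            raise ConfigError(f"unknown reference crystal {n!r}")
        c = DEFAULT_CATALOG[key]
        if c.dim != dim:
            raise ConfigError(f"crystal {n} is {c.dim}-D, system is {dim}-D")
        out.append(c)
    return out
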