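"""Shared random-sampling primitives for chain growth and CB trials.

Trial bond vectors are generated the same way everywhere (dilute-system
generation, configurational-bias regrowth): bond length uniform in the
allowed window ``[bond_min, bond_max]``, bending supplement angle drawn
from the bending Boltzmann density ``exp(-k (theta-theta0)^2) sin(theta)``
by rejection, torsion angle uniform (torsions fluctuate freely).
"""

from __future__ import annotations

import math

import numpy as np

from .interactions import InteractionSpec


def random_unit_vector(rng: np.random.Generator, dim: int = 3) -> np.ndarray:
    v = rng.normal(size=dim)
    n = np.linalg.norm(v)
    while n < 1e-12:  # pragma: no cover
        v = rng.normal(size=dim)
        n = np.linalg.norm(v)
    return v / n


def sample_bending_angle(rng: np.random.Generator, spec: InteractionSpec,
                         dim: int = 3) -> float:
    """Draw a bending supplement angle from its Boltzmann density.

    3-D density on [0, pi]: proportional to exp(-k (th - th0)^2) sin(th)
    (the sin factor is the solid-angle Jacobian).  In 2-D the Jacobian is
    flat.  ``k = 0`` reduces to the freely jointed measure.
    """
    b = spec.bending
    k, th0 = b.k_theta, b.theta0
    if k == 0.0:
        if dim == 2:
            return float(rng.uniform(0.0, math.pi))
        return float(math.acos(1.0 - 2.0 * rng.uniform()))
    s = 1.0 / math.sqrt(2.0 * k)
    while True:
        th = rng.normal(th0, s)
        if not 0.0 <= th <= math.pi:
            continue
        if dim == 2 or rng.uniform() < math.sin(th):
            return float(th)


def sample_bond_length(rng: np.random.Generator, spec: InteractionSpec) -> float:
    lo, hi = spec.bond_min, spec.bond_max
    if hi <= lo:
        return lo
    return float(rng.uniform(lo, hi))


def grow_bond_vector(
    rng: np.random.Generator,
    spec: InteractionSpec,
    prev_bond: np.ndarray | None,
    dim: int = 3,
) -> np.ndarray:
    """Trial bond vector for appending a monomer to a chain end.

    ``prev_bond`` is the bond vector pointing *toward* the current end; if
    None (chain start) the direction is uniform on the sphere/circle.
    """
    l = sample_bond_length(rng, spec)
    if prev_bond is None:
        return l * random_unit_vector(rng, dim)
    th = sample_bending_angle(rng, spec, dim)
    u = prev_bond / np.linalg.norm(prev_bond)
    if dim == 2:
        sgn = 1.0 if rng.uniform() < 0.5 else -1.0
        c, s = math.cos(th), math.sin(th) * sgn
        d = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
        return l * d
    # 3-D: rotate u away by theta around a uniform azimuth
    a = random_unit_vector(rng, 3)
    perp = a - np.dot(a, u) * u
    n = np.linalg.norm(perp)
    while n < 1e-12:  # pragma: no cover
        a = random_unit_vector(rng, 3)
        perp = a - np.dot(a, u) * u
        n = np.linalg.norm(perp)
    perp /= n
    d = math.cos(th) * u + math.sin(th) * perp
    return l * d
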