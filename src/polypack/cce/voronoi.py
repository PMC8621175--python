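"""Voronoi neighbor shells under periodic boundaries and confinement.

Neighbors of a site are the sites whose Voronoi cells share a face (a ridge
of positive area).  Periodic boundaries are handled by explicit ghost
images; confined (non-periodic) dimensions get no images, so cells at an
open boundary are unbounded there and contribute only their bounded faces.
Exactly degenerate (co-spherical) inputs such as ideal lattices are
regularized by a deterministic jitter of amplitude 1e-9, and the spurious
near-zero-area faces this creates are removed by a relative face-area
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Optional

import numpy as np
from scipy.spatial import ConvexHull, Voronoi

from ..configuration import Configuration

JITTER = 1e-9
FACE_AREA_REL_TOL = 1e-5


@dataclass
class NeighborShell:
    """Voronoi neighbors of one site, sorted by increasing distance."""

    ids: np.ndarray      # original site index of each neighbor
    vectors: np.ndarray  # displacement vectors site -> neighbor
    distances: np.ndarray

    @property
    def n_vor(self) -> int:
        return len(self.ids)


def _ghost_points(coords: np.ndarray, cell, margin: Optional[float]):
    """Original points plus periodic ghost images within ``margin`` of the box."""
    n, dim = coords.shape
    if margin is None:
        margin = 0.5 * float(np.min(cell.lengths))
    offsets = []
    for k in range(dim):
        offsets.append(
            (-cell.lengths[k], 0.0, cell.lengths[k]) if cell.periodic[k] else (0.0,)
        )
    pts = [coords]
    owner = [np.arange(n)]
    for off in product(*offsets):
        if all(o == 0.0 for o in off):
            continue
        img = coords + np.asarray(off)
        keep = np.all(
            (img > -margin) & (img < cell.lengths + margin), axis=1
        )
        if np.any(keep):
            pts.append(img[keep])
            owner.append(np.flatnonzero(keep))
    return np.vstack(pts), np.concatenate(owner)


def _ridge_area(vor: Voronoi, vidx, dim: int) -> float:
    if -1 in vidx:
        return -1.0  # unbounded ridge
    verts = vor.vertices[vidx]
    if dim == 2:
        return float(np.linalg.norm(verts[1] - verts[0]))
    c = verts.mean(axis=0)
    v = verts - c
    area = 0.0
    for a in range(len(v)):
        area += 0.5 * np.linalg.norm(np.cross(v[a], v[(a + 1) % len(v)]))
    return float(area)


def voronoi_shells(
    config: Configuration,
    margin: Optional[float] = None,
    face_tol: float = FACE_AREA_REL_TOL,
    jitter: float = JITTER,
) -> List[NeighborShell]:
    """Voronoi neighbor shells of all sites.

    ``margin`` bounds the ghost-image shell width; the default (half the
    smallest cell length) is always safe, a few sigma suffices for dense
    systems and is much faster.  Faces with relative area below
    ``face_tol`` (w.r.t. the site's largest face) are discarded as
    degeneracy artifacts.
    """
    coords = np.asarray(config.coords, dtype=float)
    n, dim = coords.shape
    rng = np.random.default_rng(12345)
    pts = coords + rng.uniform(-jitter, jitter, size=coords.shape)
    all_pts, owner = _ghost_points(pts, config.cell, margin)
    vor = Voronoi(all_pts)

    nbr_vec: list = [[] for _ in range(n)]
    nbr_id: list = [[] for _ in range(n)]
    nbr_area: list = [[] for _ in range(n)]
    for (p, q), vidx in zip(vor.ridge_points, vor.ridge_vertices):
        if p >= n and q >= n:
            continue
        area = _ridge_area(vor, vidx, dim)
        if area < 0:
            continue  # unbounded face (open confinement boundary)
        for a, b in ((p, q), (q, p)):
            if a < n:
                nbr_id[a].append(owner[b])
                nbr_vec[a].append(all_pts[b] - all_pts[a])
                nbr_area[a].append(area)

    shells = []
    for i in range(n):
        ids = np.asarray(nbr_id[i], dtype=int)
        vecs = np.asarray(nbr_vec[i], dtype=float).reshape(-1, dim)
        areas = np.asarray(nbr_area[i], dtype=float)
        if len(ids) and face_tol > 0:
            keep = areas >= face_tol * areas.max()
            ids, vecs = ids[keep], vecs[keep]
        d = np.linalg.norm(vecs, axis=1)
        order = np.argsort(d, kind="stable")
        shells.append(NeighborShell(ids[order], vecs[order], d[order]))
    return shells


def voronoi_neighbors(config: Configuration, i: int, **kw):
    """Neighbor ids and count for one site: ``(ids, N_vor(i))``."""
    shell = voronoi_shells(config, **kw)[i]
    return shell.ids, shell.n_vor


def voronoi_cell_stats(config: Configuration, margin: Optional[float] = None):
    """Per-site Voronoi cell volume/area and face count.

    Unbounded cells (open confinement) get NaN volume.  Returns a dict of
    arrays ``{"volume": ..., "faces": ...}``.
    """
    coords = np.asarray(config.coords, dtype=float)
    n, dim = coords.shape
    rng = np.random.default_rng(12345)
    pts = coords + rng.uniform(-JITTER, JITTER, size=coords.shape)
    all_pts, _ = _ghost_points(pts, config.cell, margin)
    vor = Voronoi(all_pts)
    vols = np.full(n, np.nan)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < dim + 1:
            continue
        try:
            vols[i] = ConvexHull(vor.vertices[region]).volume
        except Exception:  # degenerate flat region
            vols[i] = np.nan
    faces = np.array([s.n_vor for s in voronoi_shells(config, margin=margin)])
    return {"volume": vols, "faces": faces}
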