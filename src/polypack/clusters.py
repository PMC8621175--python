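"""Proximity clusters: Euclidean single-linkage groups of sites.

A cluster is a connected component of the graph linking site pairs whose
minimum-image distance does not exceed the linkage distance; an optional
label condition additionally requires linked sites to carry the same label
(e.g. the same crystal similarity).  Used both by the rigid-body cluster
moves and by the ordered-cluster analysis of the descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .configuration import Configuration
from .interactions import CellListGrid


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


@dataclass
class ClusterSet:
    """Connected components of the proximity graph."""

    linkage: float
    members: List[np.ndarray]
    labeled: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)

    def cluster_of(self) -> np.ndarray:
        n = int(sum(len(m) for m in self.members))
        out = np.empty(n, dtype=int)
        for ci, m in enumerate(self.members):
            out[m] = ci
        return out


def pairs_within(config: Configuration, linkage: float):
    """All site pairs (i < j) with minimum-image distance <= linkage."""
    grid = CellListGrid(config, max(linkage, 1e-9))
    cell = config.cell
    coords = config.coords
    out = []
    for i in range(config.n_sites):
        for j in grid.candidates(coords[i]):
            if j <= i:
                continue
            d = cell.min_image_displacement(coords[j] - coords[i])
            if float(np.dot(d, d)) <= linkage * linkage:
                out.append((i, j))
    return out


def detect_clusters(
    config: Configuration,
    linkage: float,
    labels: Optional[np.ndarray] = None,
) -> ClusterSet:
    """Single-linkage clusters under minimum-image proximity.

    With ``labels`` given, only equal-label pairs are linked ("same crystal
    similarity" clustering); differently labeled touching sites end up in
    different clusters.
    """
    if linkage <= 0:
        raise ValueError("linkage distance must be positive")
    n = config.n_sites
    uf = _UnionFind(n)
    for i, j in pairs_within(config, linkage):
        if labels is None or labels[i] == labels[j]:
            uf.union(i, j)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    members = [np.array(sorted(g), dtype=int) for g in groups.values()]
    members.sort(key=lambda m: (-len(m), m[0]))
    return ClusterSet(linkage, members, labeled=labels is not None)


def unwrap_cluster(config: Configuration, members: np.ndarray,
                   linkage: float) -> np.ndarray:
    """Unwrapped (periodicity-free) coordinates of one cluster.

    Anchored at the first member and propagated along the proximity graph
    with minimum-image displacements, so rigid-body geometry can be
    measured across periodic boundaries.
    """
    cell = config.cell
    coords = config.coords
    idx = {int(s): k for k, s in enumerate(members)}
    out = np.zeros((len(members), cell.dim))
    seen = {int(members[0])}
    out[0] = coords[members[0]]
    queue = [int(members[0])]
    l2 = linkage * linkage
    while queue:
        a = queue.pop()
        xa = out[idx[a]]
        for b in members:
            b = int(b)
            if b in seen:
                continue
            d = cell.min_image_displacement(coords[b] - coords[a])
            if float(np.dot(d, d)) <= l2:
                out[idx[b]] = xa + d
                seen.add(b)
                queue.append(b)
    # disconnected members (possible under label constraints): place raw
    for b in members:
        if int(b) not in seen:
            out[idx[int(b)]] = coords[b]
    return out


def gyration_shape(points: np.ndarray) -> dict:
    """Gyration-tensor metrics of a point set: Rg^2, eigenvalues, asphericity."""
    c = points.mean(axis=0)
    d = points - c
    S = d.T @ d / len(points)
    ev = np.sort(np.linalg.eigvalsh(S))[::-1]
    rg2 = float(ev.sum())
    if len(ev) == 3:
        b = float(ev[0] - 0.5 * (ev[1] + ev[2]))
    else:
        b = float(ev[0] - ev[1])
    return {
        "rg2": rg2,
        "eigenvalues": ev,
        "asphericity": b,
        "relative_asphericity": b / rg2 if rg2 > 0 else 0.0,
    }
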