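"""Cluster moves, volume-fluctuation moves and compression to jamming.

Cluster moves rigidly displace (CluDis) or rotate (CluRot) one proximity
cluster; proposals that would merge clusters (bring a foreign site within
the linkage distance) are rejected outright, which keeps every accepted
move exactly reversible.  The moves deactivate automatically when fewer
than two clusters exist.

Volume moves scale the cell and all coordinates affinely on the unconfined
dimensions (isotropic, or one random dimension in anisotropic mode) with
acceptance ``min(1, exp(-P dV + N_at ln(V'/V) - dE))``; for hard-core
systems any overlap after scaling rejects.

Compression alternates displacement sweeps with shrink attempts of
decaying amplitude; the cell volume is monotonically non-increasing and
the run stops when the relative volume change over a window falls below
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .clusters import ClusterSet, detect_clusters, unwrap_cluster
from .configuration import Configuration
from .density import packing_density
from .interactions import has_overlap
from .moves_local import attempt_monomer_displacement
from .sampling import random_unit_vector
from .system import MCSystem

ACCEPT, REJECT, SKIP = "accept", "reject", "skip"


# ------------------------------------------------------------------ #
# cluster moves
# ------------------------------------------------------------------ #
def _cluster_pair_energy(state: MCSystem, members: set) -> float:
    """Non-bonded energy between cluster members and the rest."""
    e = 0.0
    cfg = state.config
    for i in members:
        bonded = frozenset(cfg.topology.bonded_neighbors(i))
        ei = state.external_energy(
            cfg.coords[i], exclude=bonded, skip=members
        )
        if ei == math.inf:
            return math.inf
        e += ei
    return e


def _would_merge(state: MCSystem, members: set, linkage: float) -> bool:
    cfg = state.config
    l2 = linkage * linkage
    for i in members:
        for j in state.grids.overlap.candidates(cfg.coords[i]):
            if j in members:
                continue
            d = cfg.cell.min_image_displacement(cfg.coords[j] - cfg.coords[i])
            if float(np.dot(d, d)) <= l2:
                return True
    return False


def attempt_cluster_move(
    state: MCSystem,
    kind: str,
    clusters: ClusterSet | None = None,
    labels=None,
) -> str:
    """Rigid displacement (CluDis) or rotation (CluRot) of one cluster."""
    if kind not in ("CluDis", "CluRot"):
        raise ValueError(f"unknown cluster move {kind!r}")
    sched = state.schedule
    linkage = sched.cluster_linkage
    if clusters is None:
        clusters = detect_clusters(state.config, linkage, labels=labels)
    if clusters.n_clusters < 2:
        return SKIP  # automatic deactivation
    cfg = state.config
    members_arr = clusters.members[int(state.rng.integers(clusters.n_clusters))]
    members = set(int(m) for m in members_arr)
    pts = unwrap_cluster(cfg, members_arr, linkage)

    if kind == "CluDis":
        step = (
            state.rng.uniform(0.0, sched.cluster_amplitude)
            * random_unit_vector(state.rng, cfg.dim)
        )
        new_pts = pts + step
    else:
        com = pts.mean(axis=0)
        ang = state.rng.uniform(-sched.cluster_amplitude, sched.cluster_amplitude)
        if cfg.dim == 2:
            c, s = math.cos(ang), math.sin(ang)
            R = np.array([[c, -s], [s, c]])
        else:
            axis = random_unit_vector(state.rng, 3)
            c, s = math.cos(ang), math.sin(ang)
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            R = c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
        new_pts = com + (pts - com) @ R.T

    e_old = _cluster_pair_energy(state, members)
    olds = {i: cfg.coords[i].copy() for i in members}
    for k, i in enumerate(members_arr):
        state.move_site(int(i), new_pts[k])
    # clearance of the new positions (walls/fillers/closed confinement)
    if not cfg.clearance_ok(cfg.coords[members_arr]):
        ok = False
    elif _would_merge(state, members, linkage):
        ok = False  # reject outright: reverse proposal would not exist
    else:
        e_new = _cluster_pair_energy(state, members)
        ok = state.metropolis(e_new - e_old)
    if ok:
        return ACCEPT
    for i, x in olds.items():
        state.restore_site(i, x)
    return REJECT


# ------------------------------------------------------------------ #
# volume moves
# ------------------------------------------------------------------ #
def attempt_volume_move(
    state: MCSystem,
    pressure: float | None = None,
    isotropic: bool = True,
    shrink_only: bool = False,
    amplitude: float | None = None,
) -> str:
    """NPT volume-fluctuation move (affine rescale of free dimensions).

    ``shrink_only`` restricts proposals to compressions (used by the
    compaction protocol, where the pressure term is dropped and any
    non-overlapping shrink is accepted).
    """
    cfg = state.config
    cell = cfg.cell
    free = ~cell.confined_dims
    n_free = int(free.sum())
    if n_free == 0:
        return SKIP
    P = state.ensemble.pressure if pressure is None else pressure
    amp = state.schedule.volume_amplitude if amplitude is None else amplitude
    V = cell.volume
    dv = state.rng.uniform(-amp, 0.0 if shrink_only else amp) * V
    V_new = V + dv
    if V_new <= 0:
        return REJECT
    factors = np.ones(cfg.dim)
    if isotropic:
        s = (V_new / V) ** (1.0 / n_free)
        factors[free] = s
    else:
        dims = np.flatnonzero(free)
        d = dims[int(state.rng.integers(len(dims)))]
        factors[d] = V_new / V

    # isotropic scaling preserves all angles; for hard-core potentials the
    # energy change is then exactly 0 unless an overlap/bond violation
    # appears, so the two full energy sums can be skipped.
    cheap = state.spec.mode == "HS" and isotropic and state.spec.torsion is None
    e_old = 0.0 if cheap else state.total_energy()
    old_coords = cfg.coords.copy()
    old_cell = cfg.cell
    new_coords = cfg.coords * factors
    cfg.coords = new_coords
    cfg.cell = cell.scaled(factors)
    cfg.coords = cfg.cell.wrap(cfg.coords)
    state.rebuild_grids()
    per_lengths = cfg.cell.lengths[cfg.cell.periodic]
    if state.spec.hard_core and per_lengths.size and (
        per_lengths.min() < state.spec.sigma
    ):
        accept = False  # a site would overlap its own periodic image
    elif has_overlap(cfg, spec=state.spec, grids=state.grids):
        accept = False
    else:
        e_new = 0.0 if cheap else state.total_energy()
        if shrink_only:
            accept = e_new != math.inf and state.metropolis(e_new - e_old)
        else:
            arg = -P * dv + cfg.n_sites * math.log(V_new / V) - (e_new - e_old)
            accept = state.metropolis(-arg)
    if accept:
        return ACCEPT
    cfg.coords = old_coords
    cfg.cell = old_cell
    state.rebuild_grids()
    return REJECT


# ------------------------------------------------------------------ #
# compression
# ------------------------------------------------------------------ #
@dataclass
class CompressionSchedule:
    """Alternating displacement sweeps and decaying shrink attempts."""

    sweeps_per_cycle: int = 5
    initial_amplitude: float = 0.02   # max relative volume reduction
    decay: float = 0.95               # amplitude multiplier per failed window
    min_amplitude: float = 1e-7
    tolerance: float = 1e-6           # relative |dV| over a window to stop
    window: int = 20
    max_cycles: int = 5000


def compress_to_jamming(
    state: MCSystem, schedule: CompressionSchedule | None = None
):
    """Compress an athermal system until the volume stalls.

    Returns ``(phi_series, converged)``; the final configuration lives in
    ``state.config``.  The volume never increases; non-convergence within
    ``max_cycles`` returns the best state with ``converged=False``.
    """
    sched = schedule if schedule is not None else CompressionSchedule()
    cfg = state.config
    n = cfg.n_sites
    amp = sched.initial_amplitude
    phis = [packing_density(cfg)]
    window_v0 = cfg.cell.volume
    converged = False
    for cycle in range(sched.max_cycles):
        for _ in range(sched.sweeps_per_cycle * n):
            out = attempt_monomer_displacement(state)
            state.count("displacement", out)
        out = attempt_volume_move(
            state, pressure=0.0, shrink_only=True, amplitude=amp
        )
        state.count("volume", out)
        # adapt: keep shrinking eagerly while accepted, back off on
        # rejection so the protocol slows down smoothly near jamming
        if out == "accept":
            amp = min(amp * 1.05, sched.initial_amplitude)
        else:
            amp = max(amp * sched.decay, sched.min_amplitude / 10.0)
        phis.append(packing_density(cfg))
        if (cycle + 1) % sched.window == 0:
            v = cfg.cell.volume
            rel = (window_v0 - v) / window_v0
            if rel < sched.tolerance and amp <= sched.min_amplitude:
                converged = True
                break
            window_v0 = v
    return np.array(phis), converged
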