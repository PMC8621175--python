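"""Fast Monte Carlo kernels for monomeric hard-sphere systems.

The general move machinery is object-oriented and handles chains,
confinement and soft potentials; the workloads that need millions of
sweeps (compression to jamming, NPT equilibration, entropy-driven
crystallization of monomeric packings) are pure hard-sphere displacement /
volume-move loops, implemented here as numba kernels over flat arrays.
Orthorhombic periodic cells only; results are returned as plain coordinate
arrays that convert to/from :class:`~polypack.configuration.Configuration`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .cell import SimulationCell
from .configuration import Configuration
from .topology import SpeciesTopology

__all__ = [
    "hs_sweep",
    "hs_any_overlap",
    "hs_compress",
    "hs_npt",
    "hs_nvt",
    "config_from_arrays",
]


@njit(cache=True)
def _cell_index(x, y, z, ncx, ncy, ncz, lx, ly, lz):
    ix = int(x / lx * ncx)
    iy = int(y / ly * ncy)
    iz = int(z / lz * ncz)
    if ix >= ncx:
        ix = ncx - 1
    if iy >= ncy:
        iy = ncy - 1
    if iz >= ncz:
        iz = ncz - 1
    return (ix * ncy + iy) * ncz + iz


@njit(cache=True)
def _build_cells(pos, L, ncx, ncy, ncz):
    n = pos.shape[0]
    head = -np.ones(ncx * ncy * ncz, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        c = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2], ncx, ncy, ncz,
                        L[0], L[1], L[2])
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@njit(cache=True)
def _overlap_at(pos, L, sig2, i, x, y, z, head, nxt, ncx, ncy, ncz):
    ix = int(x / L[0] * ncx)
    iy = int(y / L[1] * ncy)
    iz = int(z / L[2] * ncz)
    for dx in range(-1, 2):
        jx = (ix + dx) % ncx
        for dy in range(-1, 2):
            jy = (iy + dy) % ncy
            for dz in range(-1, 2):
                jz = (iz + dz) % ncz
                j = head[(jx * ncy + jy) * ncz + jz]
                while j >= 0:
                    if j != i:
                        ddx = pos[j, 0] - x
                        ddy = pos[j, 1] - y
                        ddz = pos[j, 2] - z
                        ddx -= L[0] * round(ddx / L[0])
                        ddy -= L[1] * round(ddy / L[1])
                        ddz -= L[2] * round(ddz / L[2])
                        if ddx * ddx + ddy * ddy + ddz * ddz < sig2:
                            return True
                    j = nxt[j]
    return False


@njit(cache=True)
def hs_any_overlap(pos, L, sigma):
    """True if any periodic pair is closer than sigma (tangency allowed)."""
    n = pos.shape[0]
    ncx = max(3, int(L[0] / sigma))
    ncy = max(3, int(L[1] / sigma))
    ncz = max(3, int(L[2] / sigma))
    head, nxt = _build_cells(pos, L, ncx, ncy, ncz)
    sig2 = sigma * sigma * (1.0 - 1e-12)
    for i in range(n):
        if _overlap_at(pos, L, sig2, i, pos[i, 0], pos[i, 1], pos[i, 2],
                       head, nxt, ncx, ncy, ncz):
            return True
    return False


@njit(cache=True)
def hs_sweep(pos, L, sigma, amp, n_attempts, seed):
    """``n_attempts`` single-particle displacement attempts; returns accepts.

    Athermal acceptance: any non-overlapping move is accepted.  ``pos`` is
    modified in place and stays wrapped in [0, L).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    ncx = max(3, int(L[0] / sigma))
    ncy = max(3, int(L[1] / sigma))
    ncz = max(3, int(L[2] / sigma))
    head, nxt = _build_cells(pos, L, ncx, ncy, ncz)
    sig2 = sigma * sigma * (1.0 - 1e-12)
    acc = 0
    for _ in range(n_attempts):
        i = np.random.randint(0, n)
        x = pos[i, 0] + amp * (2.0 * np.random.random() - 1.0)
        y = pos[i, 1] + amp * (2.0 * np.random.random() - 1.0)
        z = pos[i, 2] + amp * (2.0 * np.random.random() - 1.0)
        x -= L[0] * math.floor(x / L[0])
        y -= L[1] * math.floor(y / L[1])
        z -= L[2] * math.floor(z / L[2])
        if not _overlap_at(pos, L, sig2, i, x, y, z, head, nxt, ncx, ncy, ncz):
            cold = _cell_index(pos[i, 0], pos[i, 1], pos[i, 2],
                               ncx, ncy, ncz, L[0], L[1], L[2])
            cnew = _cell_index(x, y, z, ncx, ncy, ncz, L[0], L[1], L[2])
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            if cnew != cold:
                # unlink i from its old cell
                j = head[cold]
                if j == i:
                    head[cold] = nxt[i]
                else:
                    while nxt[j] != i:
                        j = nxt[j]
                    nxt[j] = nxt[i]
                nxt[i] = head[cnew]
                head[cnew] = i
            acc += 1
    return acc


def hs_compress(
    pos: np.ndarray,
    L: np.ndarray,
    sigma: float = 1.0,
    sweeps_per_cycle: int = 5,
    initial_amplitude: float = 1e-3,
    max_amplitude: float = 5e-3,
    grow: float = 1.15,
    shrink: float = 0.75,
    min_amplitude: float = 1e-9,
    max_cycles: int = 60000,
    disp_amp: float = 0.25,
    seed: int = 0,
    target_phi: float | None = None,
):
    """Compress a monomeric HS gas toward jamming.

    Alternates displacement sweeps with isotropic shrink attempts.  The
    relative volume-shrink amplitude adapts per attempt (grows on success,
    decays on an overlap-rejected shrink), so the protocol slows down
    smoothly as the packing approaches its jammed state; the run ends when
    the amplitude collapses below ``min_amplitude`` or ``max_cycles`` is
    reached.  The displacement amplitude adapts toward ~40-55% acceptance.
    Returns ``(pos, L, phi_series)``.
    """
    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    L = L.astype(float).copy()
    amp = initial_amplitude
    phis = []
    vmon = n * math.pi / 6.0 * sigma**3
    for cycle in range(max_cycles):
        acc = hs_sweep(pos, L, sigma, disp_amp, sweeps_per_cycle * n,
                       int(rng.integers(2**31 - 1)))
        rate = acc / (sweeps_per_cycle * n)
        if rate < 0.35:
            disp_amp = max(disp_amp * 0.9, 1e-4)
        elif rate > 0.55:
            disp_amp = min(disp_amp * 1.1, 0.5 * sigma)
        s = (1.0 - amp * rng.uniform()) ** (1.0 / 3.0)
        trial = pos * s
        Lt = L * s
        if Lt.min() >= 3.0 * sigma and not hs_any_overlap(trial, Lt, sigma):
            pos[:] = trial
            L = Lt
            amp = min(amp * grow, max_amplitude)
        else:
            amp = amp * shrink
        phi = vmon / float(np.prod(L))
        phis.append(phi)
        if target_phi is not None and phi >= target_phi:
            break
        if amp < min_amplitude:
            break
    return pos, L, np.array(phis)


def hs_npt(
    pos: np.ndarray,
    L: np.ndarray,
    pressure: float,
    sigma: float = 1.0,
    n_cycles: int = 2000,
    sweeps_per_cycle: int = 2,
    disp_amp: float = 0.15,
    vol_amp: float = 0.02,
    seed: int = 0,
):
    """NPT run of monomeric hard spheres at reduced pressure P sigma^3/kT.

    One cycle = displacement sweeps + one volume move with acceptance
    ``min(1, exp(-P dV + N ln(V'/V)))``.  Returns ``(pos, L, phi_series)``.
    """
    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    L = L.astype(float).copy()
    vmon = n * math.pi / 6.0 * sigma**3
    phis = np.empty(n_cycles)
    for cycle in range(n_cycles):
        hs_sweep(pos, L, sigma, disp_amp, sweeps_per_cycle * n,
                 int(rng.integers(2**31 - 1)))
        V = float(np.prod(L))
        dv = rng.uniform(-vol_amp, vol_amp) * V
        Vn = V + dv
        if Vn > 0:
            s = (Vn / V) ** (1.0 / 3.0)
            arg = -pressure * dv + n * math.log(Vn / V)
            if arg >= 0 or rng.uniform() < math.exp(arg):
                trial = pos * s
                Lt = L * s
                if s >= 1.0 or not hs_any_overlap(trial, Lt, sigma):
                    pos[:] = trial
                    L = Lt
        phis[cycle] = vmon / float(np.prod(L))
    return pos, L, phis


def hs_nvt(pos, L, sigma=1.0, n_sweeps=1000, disp_amp=0.12, seed=0,
           snapshot_every=0, snapshot_cb=None):
    """NVT displacement-only run; optional periodic snapshot callback."""
    rng = np.random.default_rng(seed)
    n = pos.shape[0]
    for sweep in range(n_sweeps):
        hs_sweep(pos, L, sigma, disp_amp, n, int(rng.integers(2**31 - 1)))
        if snapshot_cb is not None and snapshot_every > 0 and (
            (sweep + 1) % snapshot_every == 0
        ):
            snapshot_cb(pos, sweep + 1)
    return pos


def config_from_arrays(pos: np.ndarray, L: np.ndarray, sigma: float = 1.0) -> Configuration:
    """Wrap flat monomer arrays into a Configuration."""
    cell = SimulationCell(np.asarray(L, dtype=float))
    topo = SpeciesTopology([], range(pos.shape[0]))
    return Configuration(pos, topo, cell, sigma=sigma)
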