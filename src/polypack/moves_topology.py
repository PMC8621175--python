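"""Connectivity-altering and identity-exchange Monte Carlo moves.

None of these moves displaces a single site: they delete and form properly
selected bonds.  A pair of sites can be bridged when its minimum-image
distance lies inside the bond window ``[bond_min, bond_max]`` (the
"bridgeable distance").

* sEB  -- simplified end-bridging: a chain end bonds to an interior site of
  another chain, which loses the bond on one side; both chains stay linear
  and change length.
* sIEB -- simplified intramolecular end-bridging: same rewiring within one
  chain; length is preserved.
* sDB  -- simplified double bridging: two chains exchange end segments via
  two simultaneous bridges; the length multiset is preserved, so the move
  remains applicable to strictly monodisperse systems.
* IdEx1/2/3 -- identity exchanges between single monomers and chains: a
  single monomer is absorbed at a chain end (IdEx1), next to the second or
  penultimate site (IdEx2), or at the end of one chain while a *different*
  chain releases an end (IdEx3, requires length dispersity).

Candidates are selected uniformly from the precomputed bridgeable-pair
list; the proposal asymmetry is corrected by the forward/reverse candidate
count ratio in the acceptance, together with the semigrand length-weight
ratio and the Boltzmann factor of the bonded-energy change (plus the
non-bonded terms of pairs whose bonded/non-bonded status flips).
"""

from __future__ import annotations

import math

import numpy as np

from .configuration import Configuration
from .errors import ConfigError
from .interactions import (
    InteractionSpec,
    bending_angle,
    bending_energy,
    bond_energy,
    pair_energy,
    torsion_angle,
)
from .system import MCSystem

ACCEPT, REJECT, SKIP = "accept", "reject", "skip"

_MIN_CHAIN = 2  # structural minimum chain length


# ------------------------------------------------------------------ #
# helpers
# ------------------------------------------------------------------ #
def chain_bonded_energy(cfg: Configuration, chain, spec: InteractionSpec) -> float:
    """Bond-window + bending + torsion energy of one chain."""
    e = 0.0
    coords = cfg.coords
    for a, b in zip(chain[:-1], chain[1:]):
        e += bond_energy(cfg.distance(a, b), spec)
        if e == math.inf:
            return math.inf
    if spec.bending.k_theta > 0:
        for a in range(len(chain) - 2):
            th = bending_angle(
                coords[chain[a]], coords[chain[a + 1]], coords[chain[a + 2]], cfg
            )
            e += bending_energy(th, spec)
    if spec.torsion is not None:
        for a in range(len(chain) - 3):
            phi = torsion_angle(*(coords[chain[a + k]] for k in range(4)), cfg)
            e += spec.torsion(phi)
    return e


def _within_window(state: MCSystem, i: int, j: int) -> bool:
    r = state.config.distance(i, j)
    return state.spec.bond_min - 1e-9 <= r <= state.spec.bond_max + 1e-9


def _window_neighbors(state: MCSystem, i: int):
    """Sites within the bridgeable window of site ``i``."""
    out = []
    x = state.config.coords[i]
    for j in state.grids.overlap.candidates(x):
        if j != i and _within_window(state, i, j):
            out.append(j)
    return out


def _pair_u(state: MCSystem, i: int, j: int) -> float:
    return pair_energy(state.config.distance(i, j), state.spec)


def _site_roles(cfg: Configuration):
    return cfg.topology.site_tables()  # chain_id, position, species


def _check_supported(state: MCSystem) -> None:
    if state.spec.exclude_13:
        raise ConfigError(
            "connectivity-altering/identity moves assume the default "
            "1-3-interacting convention; exclude_13 is not supported here"
        )


def _accept_topology(state, delta_e, w_ratio, n_fwd, n_rev) -> bool:
    if n_rev == 0:
        return False
    return state.metropolis(delta_e, extra_factor=w_ratio * n_fwd / n_rev)


# ------------------------------------------------------------------ #
# sEB
# ------------------------------------------------------------------ #
def _seb_candidates(state: MCSystem):
    """(chain_a, end_flag, chain_b, j, side) bridgeable-rewiring candidates.

    ``side`` selects which of the victim's bonds is deleted: 'low' keeps
    b[:j+1] attached to the bridged end, 'high' keeps b[j:].
    """
    topo = state.config.topology
    cid, pos, _ = _site_roles(state.config)
    out = []
    for ca, chain in enumerate(topo.chains):
        for end_flag, e in (("head", chain[0]), ("tail", chain[-1])):
            for m in _window_neighbors(state, e):
                cb = cid[m]
                if cb < 0 or cb == ca:
                    continue
                j = int(pos[m])
                lb = len(topo.chains[cb])
                if not 0 < j < lb - 1:
                    continue
                if j >= _MIN_CHAIN:  # piece b[0:j] survives as a chain
                    out.append((ca, end_flag, int(cb), j, "high"))
                if lb - 1 - j >= _MIN_CHAIN:  # piece b[j+1:] survives
                    out.append((ca, end_flag, int(cb), j, "low"))
    return out


def attempt_sEB(state: MCSystem) -> str:
    """Simplified end-bridging between two chains."""
    _check_supported(state)
    ens = state.ensemble
    if ens.monodisperse or state.config.topology.n_chains < 2:
        return SKIP
    cands = _seb_candidates(state)
    if not cands:
        return SKIP
    ca, end_flag, cb, j, side = cands[int(state.rng.integers(len(cands)))]
    topo = state.config.topology
    A = topo.chains[ca]
    B = topo.chains[cb]
    a_list = list(A) if end_flag == "tail" else list(reversed(A))
    if side == "low":
        new1 = a_list + list(reversed(B[: j + 1]))     # ...e-b_j-...-b_0
        new2 = B[j + 1:]
        deleted = (B[j], B[j + 1])
    else:
        new1 = a_list + B[j:]                           # ...e-b_j-...-b_end
        new2 = B[:j]
        deleted = (B[j], B[j - 1])
    formed = (a_list[-1], B[j])

    e_before = chain_bonded_energy(state.config, A, state.spec) + \
        chain_bonded_energy(state.config, B, state.spec)
    w_ratio = ens.weight_ratio([len(A), len(B)], [len(new1), len(new2)])
    if w_ratio == 0.0:
        return REJECT
    old_A, old_B = list(A), list(B)
    topo.chains[ca] = new1
    topo.chains[cb] = new2
    topo.invalidate()
    e_after = chain_bonded_energy(state.config, new1, state.spec) + \
        chain_bonded_energy(state.config, new2, state.spec)
    delta = e_after - e_before
    if delta != math.inf:
        delta += _pair_u(state, *deleted) - _pair_u(state, *formed)
    n_rev = len(_seb_candidates(state))
    if _accept_topology(state, delta, w_ratio, len(cands), n_rev):
        return ACCEPT
    topo.chains[ca] = old_A
    topo.chains[cb] = old_B
    topo.invalidate()
    return REJECT


# ------------------------------------------------------------------ #
# sIEB
# ------------------------------------------------------------------ #
def _sieb_candidates(state: MCSystem):
    """(chain_idx, end_flag, k): end bridges to interior site k of itself."""
    topo = state.config.topology
    cid, pos, _ = _site_roles(state.config)
    out = []
    for ci, chain in enumerate(topo.chains):
        L = len(chain)
        if L < 4:
            continue
        for end_flag, e in (("head", chain[0]), ("tail", chain[-1])):
            for m in _window_neighbors(state, e):
                if cid[m] != ci:
                    continue
                k = int(pos[m])
                if end_flag == "head" and 2 <= k <= L - 2:
                    out.append((ci, end_flag, k))
                elif end_flag == "tail" and 1 <= k <= L - 3:
                    out.append((ci, end_flag, k))
    return out


def attempt_sIEB(state: MCSystem) -> str:
    """Intramolecular end-bridging; chain length is preserved."""
    _check_supported(state)
    cands = _sieb_candidates(state)
    if not cands:
        return SKIP
    ci, end_flag, k = cands[int(state.rng.integers(len(cands)))]
    topo = state.config.topology
    C = topo.chains[ci]
    if end_flag == "head":
        # bridge c0-ck, delete (ck, ck-1): [ck-1..c0, ck, ck+1..]
        new = list(reversed(C[:k])) + C[k:]
        deleted = (C[k], C[k - 1])
        formed = (C[0], C[k])
    else:
        new = C[: k + 1] + list(reversed(C[k + 1:]))
        deleted = (C[k], C[k + 1])
        formed = (C[-1], C[k])

    e_before = chain_bonded_energy(state.config, C, state.spec)
    old = list(C)
    topo.chains[ci] = new
    topo.invalidate()
    e_after = chain_bonded_energy(state.config, new, state.spec)
    delta = e_after - e_before
    if delta != math.inf:
        delta += _pair_u(state, *deleted) - _pair_u(state, *formed)
    n_rev = len(_sieb_candidates(state))
    if _accept_topology(state, delta, 1.0, len(cands), n_rev):
        return ACCEPT
    topo.chains[ci] = old
    topo.invalidate()
    return REJECT


# ------------------------------------------------------------------ #
# sDB
# ------------------------------------------------------------------ #
def _sdb_candidates(state: MCSystem):
    """(ca, i, cb, j): simultaneous double bridges preserving lengths."""
    topo = state.config.topology
    out = []
    nch = topo.n_chains
    for ca in range(nch):
        A = topo.chains[ca]
        for cb in range(ca + 1, nch):
            B = topo.chains[cb]
            N, M = len(A), len(B)
            for i in range(N - 1):
                for j in range(M - 1):
                    if (i + j + 2) not in (N, M):
                        continue
                    l1, l2 = i + j + 2, N + M - i - j - 2
                    if l1 < _MIN_CHAIN or l2 < _MIN_CHAIN:
                        continue
                    if _within_window(state, A[i], B[j]) and _within_window(
                        state, A[i + 1], B[j + 1]
                    ):
                        out.append((ca, i, cb, j))
    return out


def attempt_sDB(state: MCSystem) -> str:
    """Simplified double bridging: mutual end-segment exchange."""
    _check_supported(state)
    if state.config.topology.n_chains < 2:
        return SKIP
    cands = _sdb_candidates(state)
    if not cands:
        return SKIP
    ca, i, cb, j = cands[int(state.rng.integers(len(cands)))]
    topo = state.config.topology
    A, B = topo.chains[ca], topo.chains[cb]
    new1 = A[: i + 1] + list(reversed(B[: j + 1]))
    new2 = list(reversed(B[j + 1:])) + A[i + 1:]
    formed = ((A[i], B[j]), (A[i + 1], B[j + 1]))
    deleted = ((A[i], A[i + 1]), (B[j], B[j + 1]))

    e_before = chain_bonded_energy(state.config, A, state.spec) + \
        chain_bonded_energy(state.config, B, state.spec)
    w_ratio = state.ensemble.weight_ratio(
        [len(A), len(B)], [len(new1), len(new2)]
    )
    if w_ratio == 0.0:
        return REJECT
    old_A, old_B = list(A), list(B)
    topo.chains[ca] = new1
    topo.chains[cb] = new2
    topo.invalidate()
    e_after = chain_bonded_energy(state.config, new1, state.spec) + \
        chain_bonded_energy(state.config, new2, state.spec)
    delta = e_after - e_before
    if delta != math.inf:
        delta += sum(_pair_u(state, *d) for d in deleted)
        delta -= sum(_pair_u(state, *f) for f in formed)
    n_rev = len(_sdb_candidates(state))
    if _accept_topology(state, delta, w_ratio, len(cands), n_rev):
        return ACCEPT
    topo.chains[ca] = old_A
    topo.chains[cb] = old_B
    topo.invalidate()
    return REJECT


# ------------------------------------------------------------------ #
# identity exchanges
# ------------------------------------------------------------------ #
def _single_end_candidates(state: MCSystem):
    """(single, chain_idx, end_flag) bridgeable pairs for IdEx1/IdEx3."""
    topo = state.config.topology
    cid, pos, _ = _site_roles(state.config)
    out = []
    for s in topo.singles:
        for j in _window_neighbors(state, s):
            ci = cid[j]
            if ci < 0:
                continue
            chain = topo.chains[ci]
            if j == chain[0]:
                out.append((s, int(ci), "head"))
            if j == chain[-1]:
                out.append((s, int(ci), "tail"))
    return out


def _single_inner_candidates(state: MCSystem):
    """(single, chain_idx, end_flag) pairs for IdEx2 (second/penultimate)."""
    topo = state.config.topology
    cid, pos, _ = _site_roles(state.config)
    out = []
    for s in topo.singles:
        for j in _window_neighbors(state, s):
            ci = cid[j]
            if ci < 0:
                continue
            chain = topo.chains[ci]
            if len(chain) >= 3:
                if j == chain[1]:
                    out.append((s, int(ci), "head"))
                if j == chain[-2]:
                    out.append((s, int(ci), "tail"))
    return out


def _apply_idex_swap(state, ci, end_flag, s, inner: bool):
    """Attach single ``s`` at a chain (end or next-to-end) and release the
    matching end; returns (new_chain, released, formed, deleted)."""
    topo = state.config.topology
    C = topo.chains[ci]
    if not inner:
        if end_flag == "tail":
            new = C[1:] + [s]
            released, formed, deleted = C[0], (C[-1], s), (C[0], C[1])
        else:
            new = [s] + C[:-1]
            released, formed, deleted = C[-1], (C[0], s), (C[-1], C[-2])
    else:
        if end_flag == "head":  # s bonds to C[1], C[0] released
            new = [s] + C[1:]
            released, formed, deleted = C[0], (C[1], s), (C[0], C[1])
        else:
            new = C[:-1] + [s]
            released, formed, deleted = C[-1], (C[-2], s), (C[-1], C[-2])
    return new, released, formed, deleted


def _attempt_idex_single_chain(state: MCSystem, inner: bool) -> str:
    cands = (
        _single_inner_candidates(state) if inner else _single_end_candidates(state)
    )
    if not cands:
        return SKIP
    s, ci, end_flag = cands[int(state.rng.integers(len(cands)))]
    topo = state.config.topology
    C = topo.chains[ci]
    new, released, formed, deleted = _apply_idex_swap(state, ci, end_flag, s, inner)

    e_before = chain_bonded_energy(state.config, C, state.spec)
    old_chain = list(C)
    old_singles = list(topo.singles)
    topo.chains[ci] = new
    topo.singles = sorted([x for x in topo.singles if x != s] + [released])
    topo.invalidate()
    e_after = chain_bonded_energy(state.config, new, state.spec)
    delta = e_after - e_before
    if delta != math.inf:
        delta += _pair_u(state, *deleted) - _pair_u(state, *formed)
    n_rev = len(
        _single_inner_candidates(state) if inner else _single_end_candidates(state)
    )
    if _accept_topology(state, delta, 1.0, len(cands), n_rev):
        return ACCEPT
    topo.chains[ci] = old_chain
    topo.singles = old_singles
    topo.invalidate()
    return REJECT


def attempt_IdEx(state: MCSystem, variant: int) -> str:
    """Identity-exchange move, variant 1, 2 or 3."""
    _check_supported(state)
    if variant == 1:
        return _attempt_idex_single_chain(state, inner=False)
    if variant == 2:
        return _attempt_idex_single_chain(state, inner=True)
    if variant == 3:
        return _attempt_idex3(state)
    raise ValueError(f"unknown IdEx variant {variant}")


def _attempt_idex3(state: MCSystem) -> str:
    """A single joins one chain's end; a different chain releases an end."""
    topo = state.config.topology
    ens = state.ensemble
    if ens.monodisperse or topo.n_chains < 2:
        return SKIP
    cands = _single_end_candidates(state)
    if not cands:
        return SKIP
    s, ca, end_flag = cands[int(state.rng.integers(len(cands)))]
    donors = [
        ci
        for ci in range(topo.n_chains)
        if ci != ca and len(topo.chains[ci]) > _MIN_CHAIN
    ]
    if not donors:
        return SKIP
    cc = donors[int(state.rng.integers(len(donors)))]
    C = topo.chains[cc]
    lose_tail = state.rng.uniform() < 0.5
    A = topo.chains[ca]

    w_ratio = ens.weight_ratio([len(A), len(C)], [len(A) + 1, len(C) - 1])
    if w_ratio == 0.0:
        return REJECT

    if end_flag == "tail":
        new_a = A + [s]
        formed = (A[-1], s)
    else:
        new_a = [s] + A
        formed = (A[0], s)
    if lose_tail:
        new_c = C[:-1]
        released, deleted = C[-1], (C[-1], C[-2])
    else:
        new_c = C[1:]
        released, deleted = C[0], (C[0], C[1])

    e_before = chain_bonded_energy(state.config, A, state.spec) + \
        chain_bonded_energy(state.config, C, state.spec)
    old_a, old_c, old_singles = list(A), list(C), list(topo.singles)
    topo.chains[ca] = new_a
    topo.chains[cc] = new_c
    topo.singles = sorted([x for x in topo.singles if x != s] + [released])
    topo.invalidate()
    e_after = chain_bonded_energy(state.config, new_a, state.spec) + \
        chain_bonded_energy(state.config, new_c, state.spec)
    delta = e_after - e_before
    if delta != math.inf:
        delta += _pair_u(state, *deleted) - _pair_u(state, *formed)
    n_rev = len(_single_end_candidates(state))
    # reverse donor pool: chains other than the one regaining the single
    d_rev = sum(
        1
        for ci in range(topo.n_chains)
        if ci != cc and len(topo.chains[ci]) > _MIN_CHAIN
    )
    if d_rev == 0:
        n_rev = 0
    if _accept_topology(
        state, delta, w_ratio, len(cands) * len(donors), n_rev * max(d_rev, 1)
    ):
        return ACCEPT
    topo.chains[ca] = old_a
    topo.chains[cc] = old_c
    topo.singles = old_singles
    topo.invalidate()
    return REJECT
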