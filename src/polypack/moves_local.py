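"""Localized Monte Carlo moves with optional configurational bias.

Move set: single-site displacement, flip (internal libration), end-mer
rotation, reptation, intermolecular reptation and end-segment regrowth.
The regrowth-type moves (reptation, intermolecular reptation, end regrowth)
support the configurational-bias (CB) pattern: ``n_trials`` candidate
positions are generated by the shared trial sampler (bond length uniform in
the bond window, bending angle from its Boltzmann density, azimuth
uniform), one is selected with probability proportional to its Boltzmann
weight, and the acceptance uses the ratio of summed Rosenbluth weights,
with the reverse transition rebuilt from ``n_trials - 1`` regenerated
alternatives plus the old state.  ``n_trials = 1`` reduces exactly to
conventional Metropolis execution and skips the reverse regeneration.

Trial weights contain the *external* energy only (non-bonded, walls,
fillers, plus torsion when a torsion potential is active); the bonded
bond-length and bending terms are part of the proposal density and cancel.

Every rejected move restores coordinates and neighbor grids bit-exactly;
moves whose preconditions fail (no chains, single-cluster, ...) return
``"skip"`` and are tallied separately from rejections.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .interactions import bonded_site_energy
from .sampling import grow_bond_vector, random_unit_vector
from .system import MCSystem

ACCEPT, REJECT, SKIP = "accept", "reject", "skip"


# ------------------------------------------------------------------ #
# configurational-bias primitives
# ------------------------------------------------------------------ #
def cb_select(weights: np.ndarray, rng: np.random.Generator) -> int:
    """Select a trial index with probability proportional to its weight.

    Returns -1 when all weights vanish (automatic rejection).
    """
    w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0.0:
        return -1
    return int(rng.choice(len(w), p=w / tot))


def cb_acceptance(w_new: float, w_old: float) -> float:
    """CB acceptance probability min(1, W_new / W_old)."""
    if w_old <= 0.0:
        return 1.0 if w_new > 0.0 else 0.0
    return min(1.0, w_new / w_old)


def _boltzmann(e: float) -> float:
    if e == math.inf:
        return 0.0
    return math.exp(-min(e, 700.0))


def _trial_weight(state: MCSystem, x, exclude, skip, quad=None) -> float:
    """exp(-external energy) of a trial position (optionally + torsion)."""
    e = state.external_energy(x, exclude=exclude, skip=skip)
    if e == math.inf:
        return 0.0
    if state.spec.torsion is not None and quad is not None:
        from .interactions import torsion_angle

        phi = torsion_angle(*quad, x, state.config)
        e += state.spec.torsion(phi)
    return _boltzmann(e)


# ------------------------------------------------------------------ #
# single-site displacement
# ------------------------------------------------------------------ #
def attempt_monomer_displacement(state: MCSystem, site: Optional[int] = None) -> str:
    """Displace one site by a uniform step within the preset amplitude.

    The proposal is symmetric (component-wise uniform in
    ``[-l_disp(i), l_disp(i)]``); acceptance is plain Metropolis on the
    energy change of the site, including its bonded terms for chain sites.
    """
    cfg = state.config
    if cfg.n_sites == 0:
        return SKIP
    i = int(state.rng.integers(cfg.n_sites)) if site is None else site
    amp = np.broadcast_to(
        np.asarray(state.schedule.l_disp, dtype=float), (cfg.dim,)
    )
    step = state.rng.uniform(-1.0, 1.0, size=cfg.dim) * amp
    bonded = frozenset(cfg.topology.bonded_neighbors(i))

    e_old = state.external_energy(cfg.coords[i], exclude=bonded, skip={i})
    e_old += bonded_site_energy(cfg, i, state.spec)
    old = state.move_site(i, cfg.coords[i] + step)
    e_new = state.external_energy(cfg.coords[i], exclude=bonded, skip={i})
    if e_new != math.inf:
        e_new += bonded_site_energy(cfg, i, state.spec)
    if state.metropolis(e_new - e_old):
        return ACCEPT
    state.restore_site(i, old)
    return REJECT


# ------------------------------------------------------------------ #
# flip and end rotation
# ------------------------------------------------------------------ #
def _rotate_about_axis(p, origin, axis, angle):
    u = axis / np.linalg.norm(axis)
    v = p - origin
    c, s = math.cos(angle), math.sin(angle)
    return origin + c * v + s * np.cross(u, v) + (1 - c) * np.dot(u, v) * u


def attempt_flip(state: MCSystem) -> str:
    """Rotate an interior monomer about the axis of its bonded neighbors.

    Bond lengths to both neighbors are preserved; in 2-D the move is the
    reflection of the monomer across the neighbor-neighbor line.
    """
    cfg = state.config
    chains = [c for c in cfg.topology.chains if len(c) >= 3]
    if not chains:
        return SKIP
    c = chains[int(state.rng.integers(len(chains)))]
    p = int(state.rng.integers(1, len(c) - 1))
    i, a, b = c[p], c[p - 1], c[p + 1]
    xa = cfg.coords[a]
    xi = xa + cfg.cell.min_image_displacement(cfg.coords[i] - xa)
    xb = xa + cfg.cell.min_image_displacement(cfg.coords[b] - xa)
    axis = xb - xa
    if np.linalg.norm(axis) < 1e-12:
        return SKIP
    if cfg.dim == 2:
        u = axis / np.linalg.norm(axis)
        v = xi - xa
        x_new = xa + 2.0 * np.dot(v, u) * u - v
    else:
        ang = state.rng.uniform(-state.schedule.rot_amplitude,
                                state.schedule.rot_amplitude)
        x_new = _rotate_about_axis(xi, xa, axis, ang)
    return _metropolis_site_move(state, i, x_new)


def attempt_end_rotation(state: MCSystem) -> str:
    """Re-orient a terminal bond within the angular amplitude.

    The terminal bond direction is drawn uniformly in a cone around the
    current direction and the bond length is resampled uniformly in the
    bond window; both proposals are symmetric.
    """
    cfg = state.config
    chains = [c for c in cfg.topology.chains if len(c) >= 2]
    if not chains:
        return SKIP
    c = chains[int(state.rng.integers(len(chains)))]
    e, n = (c[0], c[1]) if state.rng.uniform() < 0.5 else (c[-1], c[-2])
    v = cfg.cell.min_image_displacement(cfg.coords[e] - cfg.coords[n])
    r = np.linalg.norm(v)
    if r < 1e-12:
        return SKIP
    spec = state.spec
    length = (
        state.rng.uniform(spec.bond_min, spec.bond_max)
        if spec.bond_max > spec.bond_min
        else spec.bond_min
    )
    amp = min(state.schedule.rot_amplitude, math.pi)
    if cfg.dim == 2:
        ang = state.rng.uniform(-amp, amp)
        ca, sa = math.cos(ang), math.sin(ang)
        u = v / r
        d = np.array([ca * u[0] - sa * u[1], sa * u[0] + ca * u[1]])
    else:
        u = v / r
        cmin = math.cos(amp)
        ct = state.rng.uniform(cmin, 1.0)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        a = random_unit_vector(state.rng, 3)
        perp = a - np.dot(a, u) * u
        nn = np.linalg.norm(perp)
        if nn < 1e-12:
            return SKIP
        perp /= nn
        d = ct * u + st * perp
    x_new = cfg.coords[n] + length * d
    return _metropolis_site_move(state, e, x_new)


def _metropolis_site_move(state: MCSystem, i: int, x_new) -> str:
    cfg = state.config
    bonded = frozenset(cfg.topology.bonded_neighbors(i))
    e_old = state.external_energy(cfg.coords[i], exclude=bonded, skip={i})
    e_old += bonded_site_energy(cfg, i, state.spec)
    old = state.move_site(i, x_new)
    e_new = state.external_energy(cfg.coords[i], exclude=bonded, skip={i})
    if e_new != math.inf:
        e_new += bonded_site_energy(cfg, i, state.spec)
    if state.metropolis(e_new - e_old):
        return ACCEPT
    state.restore_site(i, old)
    return REJECT


# ------------------------------------------------------------------ #
# reptation-type CB moves
# ------------------------------------------------------------------ #
def _attach_geometry(cfg, chain, end: str):
    """Anchor position and previous-bond vector for growth at a chain end."""
    if end == "tail":
        anchor = chain[-1]
        prev = chain[-2] if len(chain) >= 2 else None
    else:
        anchor = chain[0]
        prev = chain[1] if len(chain) >= 2 else None
    x_anchor = cfg.coords[anchor]
    pb = None
    if prev is not None:
        pb = cfg.cell.min_image_displacement(x_anchor - cfg.coords[prev])
    return anchor, x_anchor, pb


def _grow_trial_set(state, x_anchor, prev_bond, n, exclude, skip, quad=None):
    """n trial positions grown from an anchor, with their weights.

    ``quad`` (three predecessor positions) is supplied only when a torsion
    potential is active, so its energy enters the trial weights.
    """
    cfg = state.config
    pos = np.empty((n, cfg.dim))
    w = np.empty(n)
    for k in range(n):
        x = cfg.cell.wrap(
            x_anchor + grow_bond_vector(state.rng, state.spec, prev_bond, cfg.dim)
        )
        pos[k] = x
        w[k] = _trial_weight(state, x, exclude, skip, quad)
    return pos, w


def _quad_for(state, chain, end_index_triplet):
    """Predecessor-position triplet for torsion-aware growth, or None."""
    if state.spec.torsion is None:
        return None
    cfg = state.config
    try:
        p2, p1, p0 = end_index_triplet
    except (TypeError, ValueError):
        return None
    if p2 is None or p1 is None or p0 is None:
        return None
    x0 = cfg.coords[p0]
    x1 = x0 + cfg.cell.min_image_displacement(cfg.coords[p1] - x0)
    x2 = x1 + cfg.cell.min_image_displacement(cfg.coords[p2] - cfg.coords[p1])
    return (x2, x1, x0)


def _exclusions(state, anchor, second):
    ex = {anchor}
    if state.spec.exclude_13 and second is not None:
        ex.add(second)
    return frozenset(ex)


def attempt_reptation(state: MCSystem) -> str:
    """Remove one chain-end monomer and regrow it at the opposite end (CB)."""
    cfg = state.config
    chains = [ci for ci, c in enumerate(cfg.topology.chains) if len(c) >= 2]
    if not chains:
        return SKIP
    ci = chains[int(state.rng.integers(len(chains)))]
    chain = cfg.topology.chains[ci]
    head_to_tail = state.rng.uniform() < 0.5
    mover = chain[0] if head_to_tail else chain[-1]
    grow_end = "tail" if head_to_tail else "head"
    n = state.schedule.trials("reptation")
    skip = frozenset({mover})

    anchor, x_anchor, pb = _attach_geometry(cfg, chain, grow_end)
    second = None
    if len(chain) >= 3:
        second = chain[-2] if grow_end == "tail" else chain[1]
    excl_new = _exclusions(state, anchor, second)
    third = None
    if len(chain) >= 4:
        third = chain[-3] if grow_end == "tail" else chain[2]
    quad_new = _quad_for(state, chain, (third, second, anchor))
    pos, w = _grow_trial_set(state, x_anchor, pb, n, excl_new, skip, quad_new)
    k = cb_select(w, state.rng)
    if k < 0:
        return REJECT

    # reverse: old position + n-1 regenerated trials at the vacated end
    old_anchor = chain[1] if head_to_tail else chain[-2]
    old_second = chain[2] if (head_to_tail and len(chain) >= 3) else (
        chain[-3] if (not head_to_tail and len(chain) >= 3) else None
    )
    excl_old = _exclusions(state, old_anchor, old_second)
    old_third = None
    if len(chain) >= 4:
        old_third = chain[3] if head_to_tail else chain[-4]
    quad_old = _quad_for(state, chain, (old_third, old_second, old_anchor))
    w_old = _trial_weight(state, cfg.coords[mover], excl_old, skip, quad_old)
    if n > 1:
        x_oa = cfg.coords[old_anchor]
        pb_old = None
        if len(chain) >= 3:
            nxt = chain[2] if head_to_tail else chain[-3]
            pb_old = cfg.cell.min_image_displacement(x_oa - cfg.coords[nxt])
        _, w_rev = _grow_trial_set(state, x_oa, pb_old, n - 1, excl_old, skip, quad_old)
        w_old += w_rev.sum()

    if state.rng.uniform() >= cb_acceptance(w.sum(), w_old):
        return REJECT
    state.move_site(mover, pos[k])
    if head_to_tail:
        chain.pop(0)
        chain.append(mover)
    else:
        chain.pop()
        chain.insert(0, mover)
    cfg.topology.invalidate()
    return ACCEPT


def attempt_inter_reptation(state: MCSystem) -> str:
    """Transfer a chain-end monomer to another chain's end (CB, semigrand).

    Both chain lengths change by one; the acceptance carries the target
    length-distribution weight ratio, so the move requires (and drives)
    length dispersity.
    """
    cfg = state.config
    topo = cfg.topology
    if topo.n_chains < 2:
        return SKIP
    n_min_struct = 2
    donors = [ci for ci, c in enumerate(topo.chains) if len(c) > n_min_struct]
    if not donors:
        return SKIP
    ci = donors[int(state.rng.integers(len(donors)))]
    cj = int(state.rng.integers(topo.n_chains - 1))
    if cj >= ci:
        cj += 1
    a, b = topo.chains[ci], topo.chains[cj]
    donor_head = state.rng.uniform() < 0.5
    acceptor_tail = state.rng.uniform() < 0.5
    mover = a[0] if donor_head else a[-1]

    ratio = state.ensemble.weight_ratio(
        [len(a), len(b)], [len(a) - 1, len(b) + 1]
    )
    if ratio == 0.0:
        return REJECT

    n = state.schedule.trials("inter_reptation")
    skip = frozenset({mover})
    grow_end = "tail" if acceptor_tail else "head"
    anchor, x_anchor, pb = _attach_geometry(cfg, b, grow_end)
    second = None
    if len(b) >= 2:
        second = b[-2] if acceptor_tail else b[1]
    excl_new = _exclusions(state, anchor, second)
    third = None
    if len(b) >= 3:
        third = b[-3] if acceptor_tail else b[2]
    quad_new = _quad_for(state, b, (third, second, anchor))
    pos, w = _grow_trial_set(state, x_anchor, pb, n, excl_new, skip, quad_new)
    k = cb_select(w, state.rng)
    if k < 0:
        return REJECT

    old_anchor = a[1] if donor_head else a[-2]
    old_second = None
    if len(a) >= 3:
        old_second = a[2] if donor_head else a[-3]
    excl_old = _exclusions(state, old_anchor, old_second)
    old_third = None
    if len(a) >= 4:
        old_third = a[3] if donor_head else a[-4]
    quad_old = _quad_for(state, a, (old_third, old_second, old_anchor))
    w_old = _trial_weight(state, cfg.coords[mover], excl_old, skip, quad_old)
    if n > 1:
        x_oa = cfg.coords[old_anchor]
        pb_old = None
        if len(a) >= 3:
            nxt = a[2] if donor_head else a[-3]
            pb_old = cfg.cell.min_image_displacement(x_oa - cfg.coords[nxt])
        _, w_rev = _grow_trial_set(state, x_oa, pb_old, n - 1, excl_old, skip, quad_old)
        w_old += w_rev.sum()

    if state.rng.uniform() >= cb_acceptance(ratio * w.sum(), w_old):
        return REJECT
    state.move_site(mover, pos[k])
    if donor_head:
        a.pop(0)
    else:
        a.pop()
    if acceptor_tail:
        b.append(mover)
    else:
        b.insert(0, mover)
    cfg.topology.invalidate()
    return ACCEPT


def attempt_end_regrow(state: MCSystem) -> str:
    """Regrow up to ``max_regrow`` terminal monomers of a chain end (CB)."""
    cfg = state.config
    chains = [ci for ci, c in enumerate(cfg.topology.chains) if len(c) >= 2]
    if not chains:
        return SKIP
    ci = chains[int(state.rng.integers(len(chains)))]
    chain = cfg.topology.chains[ci]
    mmax = min(state.schedule.max_regrow, len(chain) - 1)
    m = int(state.rng.integers(1, mmax + 1))
    at_tail = state.rng.uniform() < 0.5
    seq = chain[-m:] if at_tail else list(reversed(chain[:m]))
    n = state.schedule.trials("end_regrow")

    # reverse Rosenbluth weight first, from the current (old) coordinates
    w_old_total = 1.0
    for s, site in enumerate(seq):
        skip = frozenset(seq[s + 1:])
        prev1, prev2 = _regrow_anchors(chain, m, s, at_tail)
        excl = _exclusions(state, prev1, prev2)
        w_here = _trial_weight(state, cfg.coords[site], excl, skip | {site})
        if n > 1:
            x_anchor = cfg.coords[prev1]
            pb = None
            if prev2 is not None:
                pb = cfg.cell.min_image_displacement(
                    x_anchor - cfg.coords[prev2]
                )
            _, w_rev = _grow_trial_set(
                state, x_anchor, pb, n - 1, excl, skip | {site}
            )
            w_here += w_rev.sum()
        w_old_total *= w_here
        if w_old_total == 0.0:
            break

    # forward growth
    olds = {site: cfg.coords[site].copy() for site in seq}
    w_new_total = 1.0
    grown = []
    for s, site in enumerate(seq):
        skip = frozenset(seq[s + 1:])
        prev1, prev2 = _regrow_anchors(chain, m, s, at_tail)
        excl = _exclusions(state, prev1, prev2)
        x_anchor = cfg.coords[prev1]
        pb = None
        if prev2 is not None:
            pb = cfg.cell.min_image_displacement(x_anchor - cfg.coords[prev2])
        pos, w = _grow_trial_set(state, x_anchor, pb, n, excl, skip | {site})
        k = cb_select(w, state.rng)
        if k < 0:
            w_new_total = 0.0
            break
        w_new_total *= w.sum()
        state.move_site(site, pos[k])
        grown.append(site)

    if w_new_total > 0.0 and state.rng.uniform() < cb_acceptance(
        w_new_total, w_old_total
    ):
        return ACCEPT
    for site in grown:
        state.restore_site(site, olds[site])
    return REJECT


def _regrow_anchors(chain, m, s, at_tail):
    """(bonded anchor, second-from-anchor) for regrowth step ``s``."""
    L = len(chain)
    if at_tail:
        idx = L - m + s
        prev1 = chain[idx - 1]
        prev2 = chain[idx - 2] if idx >= 2 else None
    else:
        idx = m - 1 - s
        prev1 = chain[idx + 1]
        prev2 = chain[idx + 2] if idx + 2 < L else None
    return prev1, prev2


_CHAIN_MOVES = {
    "flip": attempt_flip,
    "end_rotation": attempt_end_rotation,
    "reptation": attempt_reptation,
    "inter_reptation": attempt_inter_reptation,
    "end_regrow": attempt_end_regrow,
}


def attempt_chain_move(state: MCSystem, move: str) -> str:
    """Dispatch one of the chain moves by name."""
    try:
        fn = _CHAIN_MOVES[move]
    except KeyError:
        raise ValueError(f"unknown chain move {move!r}") from None
    return fn(state)
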