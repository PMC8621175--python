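"""Top-level Monte Carlo driver: dispatch moves according to a schedule."""

from __future__ import annotations

from typing import Callable, Optional

from .moves_collective import attempt_cluster_move, attempt_volume_move
from .moves_local import (
    attempt_chain_move,
    attempt_monomer_displacement,
)
from .moves_topology import attempt_IdEx, attempt_sDB, attempt_sEB, attempt_sIEB
from .system import MCSystem

_DISPATCH: dict[str, Callable[[MCSystem], str]] = {
    "displacement": attempt_monomer_displacement,
    "flip": lambda s: attempt_chain_move(s, "flip"),
    "end_rotation": lambda s: attempt_chain_move(s, "end_rotation"),
    "reptation": lambda s: attempt_chain_move(s, "reptation"),
    "inter_reptation": lambda s: attempt_chain_move(s, "inter_reptation"),
    "end_regrow": lambda s: attempt_chain_move(s, "end_regrow"),
    "seb": attempt_sEB,
    "sieb": attempt_sIEB,
    "sdb": attempt_sDB,
    "idex1": lambda s: attempt_IdEx(s, 1),
    "idex2": lambda s: attempt_IdEx(s, 2),
    "idex3": lambda s: attempt_IdEx(s, 3),
    "cluster_displacement": lambda s: attempt_cluster_move(s, "CluDis"),
    "cluster_rotation": lambda s: attempt_cluster_move(s, "CluRot"),
    "volume": lambda s: attempt_volume_move(s),
}


def effective_probabilities(state: MCSystem) -> dict:
    """Schedule probabilities with ensemble-deactivated moves removed.

    Monodisperse mode drops the length-changing moves (sEB,
    intermolecular reptation, IdEx3); the remainder is renormalized.
    """
    off = set(state.ensemble.deactivated_moves())
    probs = {
        m: p for m, p in state.schedule.probabilities.items() if m not in off
    }
    tot = sum(probs.values())
    if tot <= 0:
        raise ValueError("no active moves remain in the schedule")
    return {m: p / tot for m, p in probs.items()}


def mc_step(state: MCSystem, probs: Optional[dict] = None) -> tuple[str, str]:
    """Attempt one move drawn from the schedule; returns (move, outcome)."""
    if probs is None:
        probs = effective_probabilities(state)
    names = list(probs)
    import numpy as np

    p = np.array([probs[m] for m in names])
    move = names[int(state.rng.choice(len(names), p=p))]
    outcome = _DISPATCH[move](state)
    state.count(move, outcome)
    return move, outcome


def run(
    state: MCSystem,
    n_steps: int,
    callback: Optional[Callable[[MCSystem, int], None]] = None,
    callback_every: int = 0,
) -> MCSystem:
    """Run ``n_steps`` move attempts, invoking ``callback`` periodically."""
    probs = effective_probabilities(state)
    names = list(probs)
    import numpy as np

    p = np.array([probs[m] for m in names])
    for step in range(n_steps):
        move = names[int(state.rng.choice(len(names), p=p))]
        outcome = _DISPATCH[move](state)
        state.count(move, outcome)
        if callback is not None and callback_every > 0 and (
            (step + 1) % callback_every == 0
        ):
            callback(state, step + 1)
    return state
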