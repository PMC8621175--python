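"""Mutable Monte Carlo system state shared by all move families."""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .configuration import Configuration
from .ensemble import EnsembleSpec
from .interactions import (
    InteractionSpec,
    NeighborGrids,
    pair_energy,
    total_energy,
)
from .schedule import MoveSchedule


class MCSystem:
    """Configuration + interaction spec + neighbor grids + RNG + statistics.

    All move functions mutate this object in place and keep the neighbor
    grids synchronized with the coordinates; a rejected move restores the
    previous state bit-exactly.
    """

    def __init__(
        self,
        config: Configuration,
        spec: InteractionSpec | None = None,
        ensemble: EnsembleSpec | None = None,
        schedule: MoveSchedule | None = None,
        rng: np.random.Generator | int | None = None,
    ):
        self.config = config
        self.spec = spec if spec is not None else InteractionSpec()
        self.ensemble = ensemble if ensemble is not None else EnsembleSpec()
        self.schedule = schedule if schedule is not None else MoveSchedule()
        if isinstance(rng, np.random.Generator):
            self.rng = rng
        else:
            self.rng = np.random.default_rng(
                self.schedule.seed if rng is None else rng
            )
        self.grids = NeighborGrids(config, self.spec)
        self.stats: dict[str, dict] = {}

    # -------------------------------------------------------------- #
    def count(self, move: str, outcome: str) -> None:
        rec = self.stats.setdefault(
            move, {"attempts": 0, "accepts": 0, "skips": 0}
        )
        rec["attempts"] += 1
        if outcome == "accept":
            rec["accepts"] += 1
        elif outcome == "skip":
            rec["skips"] += 1

    def acceptance_rates(self) -> dict:
        out = {}
        for m, rec in self.stats.items():
            att = rec["attempts"] - rec["skips"]
            out[m] = rec["accepts"] / att if att > 0 else float("nan")
        return out

    # -------------------------------------------------------------- #
    def move_site(self, i: int, x_new: np.ndarray) -> np.ndarray:
        """Move site ``i``; returns the previous position for restore."""
        old = self.config.coords[i].copy()
        x = self.config.cell.wrap(x_new)
        self.config.coords[i] = x
        self.grids.move(i, x)
        return old

    def restore_site(self, i: int, old: np.ndarray) -> None:
        self.config.coords[i] = old
        self.grids.move(i, old)

    def rebuild_grids(self) -> None:
        self.grids = NeighborGrids(self.config, self.spec)

    def total_energy(self) -> float:
        return total_energy(self.config, self.spec, self.grids)

    def metropolis(self, delta_e: float, extra_factor: float = 1.0) -> bool:
        """Accept with probability min(1, extra_factor * exp(-delta_e))."""
        if extra_factor <= 0.0 or delta_e == math.inf:
            return False
        if delta_e == -math.inf:
            return True
        p = extra_factor * math.exp(-min(delta_e, 700.0))
        return p >= 1.0 or self.rng.uniform() < p

    # -------------------------------------------------------------- #
    def external_energy(
        self,
        x: np.ndarray,
        exclude: frozenset | set = frozenset(),
        skip: frozenset | set = frozenset(),
    ) -> float:
        """Non-bonded + wall/filler energy of a (trial) position.

        ``exclude`` are bonded partners (no pair term, but their bond
        window is not checked here); ``skip`` are sites ignored entirely
        (e.g. the site being regrown).  Infinite for clearance violations
        and hard-core overlaps.
        """
        cfg = self.config
        if not cfg.clearance_ok(x):
            return math.inf
        e = 0.0
        rc = self.spec.cutoff
        for j in self.grids.energy.candidates(x):
            if j in skip or j in exclude:
                continue
            d = cfg.cell.min_image_displacement(cfg.coords[j] - x)
            r = float(np.linalg.norm(d))
            if r < rc + 1e-9:
                e += pair_energy(r, self.spec)
                if e == math.inf:
                    return math.inf
        return e
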