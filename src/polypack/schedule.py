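"""Move schedules: attempt probabilities, CB trial counts, amplitudes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import ConfigError

KNOWN_MOVES = (
    "displacement",
    "flip",
    "end_rotation",
    "reptation",
    "inter_reptation",
    "end_regrow",
    "seb",
    "sieb",
    "sdb",
    "idex1",
    "idex2",
    "idex3",
    "cluster_displacement",
    "cluster_rotation",
    "volume",
)


@dataclass
class MoveSchedule:
    """Per-move attempt probabilities, CB trial counts and amplitudes.

    ``n_trials`` defaults to 1 for every move (conventional Metropolis
    execution); values > 1 switch the regrowth-type moves to the
    configurational-bias pattern.  ``l_disp`` is the per-dimension
    displacement amplitude; angular amplitudes are in radians.
    """

    probabilities: Dict[str, float] = field(
        default_factory=lambda: {"displacement": 1.0}
    )
    n_trials: Dict[str, int] = field(default_factory=dict)
    l_disp: float | np.ndarray = 0.3
    rot_amplitude: float = np.pi / 4
    cluster_amplitude: float = 1.0
    cluster_linkage: float = 1.05
    volume_amplitude: float = 0.05   # max |dV| as a fraction of V
    max_regrow: int = 3              # end_regrow: max terminal segments
    seed: int = 0

    def __post_init__(self):
        for m in self.probabilities:
            if m not in KNOWN_MOVES:
                raise ConfigError(f"unknown move {m!r}")
        tot = sum(self.probabilities.values())
        if tot <= 0:
            raise ConfigError("move probabilities must sum to a positive value")
        self.probabilities = {m: p / tot for m, p in self.probabilities.items()}
        for m, k in self.n_trials.items():
            if m not in KNOWN_MOVES:
                raise ConfigError(f"unknown move {m!r}")
            if k < 1:
                raise ConfigError("n_trials must be >= 1")

    def trials(self, move: str) -> int:
        return int(self.n_trials.get(move, 1))

    def pick(self, rng: np.random.Generator) -> str:
        names = list(self.probabilities)
        p = np.array([self.probabilities[m] for m in names])
        return names[rng.choice(len(names), p=p)]


@dataclass
class RosenbluthRecord:
    """Forward/reverse trial bookkeeping of one CB move.

    The forward record holds the ``n_trials`` trial positions and their
    Boltzmann weights, with ``chosen`` the selected trial; the reverse
    record holds ``n_trials - 1`` regenerated alternatives plus the old
    state (by convention the old state is entry 0).
    """

    forward_positions: np.ndarray
    forward_weights: np.ndarray
    chosen: int
    reverse_weights: np.ndarray

    @property
    def w_new(self) -> float:
        return float(self.forward_weights.sum())

    @property
    def w_old(self) -> float:
        return float(self.reverse_weights.sum())
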