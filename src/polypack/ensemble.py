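"""Statistical ensembles and chain-length-distribution control.

Supported ensembles: NVT, NPT (isotropic or anisotropic volume moves at
pressure P in k_B*T/sigma^3) and the semigrand ensemble in which the site
and chain counts are fixed but the chain-length distribution fluctuates,
controlled by relative chemical potentials.  The chemical-potential
spectrum is encoded, equivalently, as target length-distribution weights
``w(N)`` on ``[N_min, N_max]``: every move that changes chain lengths
carries the factor ``prod w(N_new) / prod w(N_old)`` in its acceptance.

Families:

* ``uniform`` -- w(N) constant on the window;
* ``flory``   -- most-probable distribution, w(N) proportional to p^N with
  ``p = 1 - 1/<N>`` for a target mean length <N>, truncated to the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError


@dataclass(frozen=True)
class LengthDistribution:
    """Target chain-length weights w(N) > 0 on [n_min, n_max], 0 outside."""

    family: str = "uniform"          # uniform | flory
    n_min: int = 1
    n_max: int = 10**9
    mean: Optional[float] = None     # Flory target mean length

    def __post_init__(self):
        if self.family not in ("uniform", "flory"):
            raise ConfigError(f"unknown length-distribution family {self.family!r}")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ConfigError("need 1 <= n_min <= n_max")
        if self.family == "flory" and (self.mean is None or self.mean <= 1):
            raise ConfigError("flory distribution needs a mean length > 1")

    def weight(self, n: int) -> float:
        if not self.n_min <= n <= self.n_max:
            return 0.0
        if self.family == "uniform":
            return 1.0
        p = 1.0 - 1.0 / float(self.mean)
        return p**n


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble choice plus its parameters."""

    kind: str = "NVT"                # NVT | NPT | semigrand
    pressure: float = 0.0            # k_B*T / sigma^3 (NPT)
    lengths: LengthDistribution = LengthDistribution()
    monodisperse: bool = False

    def __post_init__(self):
        if self.kind not in ("NVT", "NPT", "semigrand"):
            raise ConfigError(f"unknown ensemble {self.kind!r}")

    def weight_ratio(self, old_lengths, new_lengths) -> float:
        """prod w(N_new) / prod w(N_old) for a length-changing move.

        In monodisperse mode any length change is forbidden (ratio 0 unless
        lengths are unchanged as multisets).
        """
        if self.monodisperse:
            return 1.0 if sorted(old_lengths) == sorted(new_lengths) else 0.0
        num = 1.0
        for n in new_lengths:
            num *= self.lengths.weight(int(n))
        if num == 0.0:
            return 0.0
        den = 1.0
        for n in old_lengths:
            den *= self.lengths.weight(int(n))
        return num / den if den > 0 else 0.0

    def deactivated_moves(self) -> tuple:
        """Moves incompatible with strict monodispersity."""
        if self.monodisperse:
            return ("seb", "inter_reptation", "idex3")
        return ()
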