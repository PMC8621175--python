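"""Chain/monomer species bookkeeping.

A system holds ``N_ch`` linear chains plus ``N_s`` single (unbonded)
monomers, with ``N_ch * N + N_s = N_at`` where ``N`` is the mean chain
length.  Chains are simple paths; the bond graph is a disjoint union of
paths, which every connectivity-altering move must preserve.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np

from .errors import TopologyError

CHAIN_MONOMER = "C"
SINGLE_MONOMER = "S"


class SpeciesTopology:
    """Mutable chain topology over sites ``0..N_at-1``.

    Parameters
    ----------
    chains : iterable of site-index sequences
        Each chain is the ordered list of its member sites.
    singles : sequence of int
        Sites that are unbonded single monomers.
    """

    def __init__(self, chains: Iterable[Sequence[int]], singles: Sequence[int] = ()):
        self.chains: List[List[int]] = [list(map(int, c)) for c in chains]
        self.singles: List[int] = sorted(int(s) for s in singles)
        self._tables = None
        self.validate()

    # ------------------------------------------------------------------ #
    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_singles(self) -> int:
        return len(self.singles)

    @property
    def n_sites(self) -> int:
        return sum(len(c) for c in self.chains) + len(self.singles)

    @property
    def mean_chain_length(self) -> float:
        if not self.chains:
            return 0.0
        return sum(len(c) for c in self.chains) / len(self.chains)

    def chain_lengths(self) -> np.ndarray:
        return np.array([len(c) for c in self.chains], dtype=int)

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        """Check that every site appears exactly once and chains are paths."""
        seen = set()
        for c in self.chains:
            if len(c) < 2:
                raise TopologyError("chains must contain at least 2 sites")
            for s in c:
                if s in seen:
                    raise TopologyError(f"site {s} appears more than once")
                seen.add(s)
        for s in self.singles:
            if s in seen:
                raise TopologyError(f"site {s} appears more than once")
            seen.add(s)
        if seen and seen != set(range(len(seen))):
            raise TopologyError("site indices must be 0..N_at-1")

    def bonds(self) -> np.ndarray:
        """All bonds as an ``(n_bonds, 2)`` integer array."""
        out = []
        for c in self.chains:
            out.extend(zip(c[:-1], c[1:]))
        return np.array(out, dtype=int).reshape(-1, 2)

    def invalidate(self) -> None:
        """Drop cached per-site tables after a topology mutation.

        Every move that rewires chains (or reorders their site lists)
        must call this; the local moves that only displace sites need not.
        """
        self._tables = None

    def site_tables(self):
        """Per-site arrays ``(chain_id, position_in_chain, species)``.

        ``chain_id`` is -1 and ``position`` is 0 for single monomers;
        species is ``"C"`` for chain monomers and ``"S"`` for singles.
        Cached; see :meth:`invalidate`.
        """
        if self._tables is not None:
            return self._tables
        n = self.n_sites
        chain_id = np.full(n, -1, dtype=int)
        pos = np.zeros(n, dtype=int)
        species = np.full(n, SINGLE_MONOMER, dtype="U1")
        for ci, c in enumerate(self.chains):
            for pi, s in enumerate(c):
                chain_id[s] = ci
                pos[s] = pi
                species[s] = CHAIN_MONOMER
        self._tables = (chain_id, pos, species)
        return self._tables

    def bonded_neighbors(self, i: int):
        """Bonded neighbor site indices of site ``i`` (0, 1 or 2 of them)."""
        cid, pos, _ = self.site_tables()
        if cid[i] < 0:
            return []
        c = self.chains[cid[i]]
        p = pos[i]
        out = []
        if p > 0:
            out.append(c[p - 1])
        if p < len(c) - 1:
            out.append(c[p + 1])
        return out

    def copy(self) -> "SpeciesTopology":
        return SpeciesTopology([list(c) for c in self.chains], list(self.singles))

    @classmethod
    def from_uniform(cls, n_chains: int, chain_length: int, n_singles: int = 0):
        """Monodisperse topology: chains first, singles after."""
        chains = []
        k = 0
        for _ in range(n_chains):
            chains.append(list(range(k, k + chain_length)))
            k += chain_length
        singles = list(range(k, k + n_singles))
        return cls(chains, singles)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SpeciesTopology)
            and self.chains == other.chains
            and self.singles == other.singles
        )
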