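"""Dilute non-overlapping system generation.

Initial configurations are built under dilute conditions as non-reversal
random walks (chains) plus uniformly placed single monomers, honoring the
hard-core, bond-window, wall-clearance and filler-clearance constraints.
Dense states are then reached by compression or NPT simulation, never by
direct dense insertion.
"""

from __future__ import annotations

import numpy as np

from .cell import SimulationCell
from .configuration import Configuration
from .errors import GenerationError
from .interactions import CellListGrid, InteractionSpec
from .sampling import grow_bond_vector
from .topology import SpeciesTopology


def _site_ok(x, placed, grid, cell, fillers, sigma, bonded_prev=None, spec=None):
    """Clearance + hard-core test for a candidate position."""
    half = sigma / 2.0
    if cell.d_conf and float(cell.surface_clearance(x)[0]) < half - 1e-12:
        return False
    for f in fillers:
        if float(f.surface_distance(x, cell)[0]) < half - 1e-12:
            return False
    for j in grid.candidates(x):
        d = cell.min_image_displacement(placed[j] - x)
        r = float(np.linalg.norm(d))
        if j == bonded_prev:
            if not (spec.bond_min - 1e-9 <= r <= spec.bond_max + 1e-9):
                return False
        elif r < sigma - 1e-9:
            return False
    return True


def generate_dilute_system(
    n_chains: int,
    chain_length: int,
    n_singles: int,
    cell: SimulationCell,
    spec: InteractionSpec | None = None,
    seed: int = 0,
    fillers=(),
    max_site_trials: int = 60,
    max_chain_restarts: int = 200,
) -> Configuration:
    """Generate a non-overlapping chain/monomer system.

    Chains are grown monomer by monomer with the shared trial-vector
    sampler (bond length uniform in the bond window, bending angle from
    its Boltzmann density, azimuth uniform); singles are placed uniformly.
    Deterministic for a fixed seed.

    Raises
    ------
    GenerationError
        If placement repeatedly fails; the cell is then too small for the
        requested site count at these constraints.
    """
    spec = spec if spec is not None else InteractionSpec()
    rng = np.random.default_rng(seed)
    sigma = spec.sigma
    dim = cell.dim
    n_at = n_chains * chain_length + n_singles
    placed = np.empty((n_at, dim))
    grid = CellListGrid(cell, max(sigma, spec.bond_max))
    count = 0

    def random_point():
        return rng.uniform(0.0, 1.0, size=dim) * cell.lengths

    chains = []
    for _ in range(n_chains):
        for _restart in range(max_chain_restarts):
            start = count
            ok = True
            for m in range(chain_length):
                placed_m = False
                for _try in range(max_site_trials):
                    if m == 0:
                        x = random_point()
                        prev = None
                    else:
                        prev = count - 1
                        if m == 1:
                            pb = None
                        else:
                            pb = cell.min_image_displacement(
                                placed[count - 1] - placed[count - 2]
                            )
                        x = cell.wrap(placed[prev] + grow_bond_vector(rng, spec, pb, dim))
                    if _site_ok(x, placed, grid, cell, fillers, sigma, prev, spec):
                        placed[count] = x
                        grid.insert(count, x)
                        count += 1
                        placed_m = True
                        break
                if not placed_m:
                    ok = False
                    break
            if ok:
                chains.append(list(range(start, start + chain_length)))
                break
            # tear the partial chain down and retry
            for i in range(start, count):
                grid.remove(i)
            count = start
        else:
            raise GenerationError(
                "chain placement failed; use a larger cell or shorter chains"
            )

    singles = []
    for _ in range(n_singles):
        for _try in range(max_site_trials * 50):
            x = random_point()
            if _site_ok(x, placed, grid, cell, fillers, sigma, None, spec):
                placed[count] = x
                grid.insert(count, x)
                singles.append(count)
                count += 1
                break
        else:
            raise GenerationError(
                "single-monomer placement failed; use a larger cell"
            )

    topo = SpeciesTopology(chains, singles)
    return Configuration(placed[:n_at], topo, cell, fillers=fillers, sigma=sigma)
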