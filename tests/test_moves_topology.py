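"""Connectivity-altering and identity-exchange moves: conservation laws,
graph validity, toy-system stationary distributions."""

import math

import networkx as nx
import numpy as np
import pytest

from polypack.cell import SimulationCell
from polypack.configuration import Configuration
from polypack.ensemble import EnsembleSpec, LengthDistribution
from polypack.generate import generate_dilute_system
from polypack.interactions import InteractionSpec, has_overlap
from polypack.moves_topology import (
    attempt_IdEx,
    attempt_sDB,
    attempt_sEB,
    attempt_sIEB,
)
from polypack.sampler import run
from polypack.schedule import MoveSchedule
from polypack.system import MCSystem
from polypack.topology import SpeciesTopology


def _blend_state(seed=0, n_chains=6, N=6, n_singles=12, phi=0.08, dl=0.15,
                 lengths=None, monodisperse=False):
    n_at = n_chains * N + n_singles
    L = (n_at * math.pi / 6.0 / phi) ** (1.0 / 3.0)
    spec = InteractionSpec(dl=dl)
    cfg = generate_dilute_system(
        n_chains, N, n_singles, SimulationCell([L] * 3), spec, seed=seed
    )
    ens = EnsembleSpec(
        kind="semigrand",
        lengths=lengths or LengthDistribution("uniform", 2, 4 * N),
        monodisperse=monodisperse,
    )
    sched = MoveSchedule(
        probabilities={
            "displacement": 0.3,
            "reptation": 0.2,
            "seb": 0.15,
            "sieb": 0.1,
            "sdb": 0.05,
            "idex1": 0.08,
            "idex2": 0.06,
            "idex3": 0.06,
        },
        seed=seed,
    )
    return MCSystem(cfg, spec, ens, sched)


def _graph_is_paths(topology):
    """Independent oracle: the bond graph is a disjoint union of simple
    paths that match the stored chain lists."""
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_sites))
    g.add_edges_from(map(tuple, topology.bonds()))
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        degs = [d for _, d in sub.degree()]
        if len(comp) == 1:
            continue
        if sorted(degs)[:2] != [1, 1] or max(degs) > 2:
            return False
        if sub.number_of_edges() != len(comp) - 1:
            return False
    chain_sets = {frozenset(c) for c in topology.chains}
    comp_sets = {
        frozenset(c) for c in nx.connected_components(g) if len(c) > 1
    }
    return chain_sets == comp_sets


class TestConservationLaws:
    def test_mixed_run_conserves_counts_and_path_topology(self):
        state = _blend_state(seed=1)
        topo = state.config.topology
        n_at = topo.n_sites
        for block in range(8):
            run(state, 400)
            topo.validate()
            assert topo.n_sites == n_at
            assert _graph_is_paths(topo)
            assert not has_overlap(
                state.config, spec=state.spec, grids=state.grids
            )

    def test_seb_conserves_chain_count_and_window(self):
        state = _blend_state(seed=2, n_singles=0, phi=0.18)
        topo = state.config.topology
        nch, ns = topo.n_chains, topo.n_singles
        accepted = 0
        for _ in range(3000):
            out = attempt_sEB(state)
            accepted += out == "accept"
            assert topo.n_chains == nch
            assert topo.n_singles == ns
        lengths = topo.chain_lengths()
        assert lengths.min() >= 2 and lengths.max() <= 24
        assert accepted > 0  # dense enough to bridge

    def test_sieb_preserves_chain_length_and_runs_monodisperse(self):
        state = _blend_state(seed=3, n_chains=4, N=10, n_singles=0, phi=0.15,
                             monodisperse=True)
        topo = state.config.topology
        before = sorted(topo.chain_lengths())
        outcomes = {attempt_sIEB(state) for _ in range(2000)}
        assert sorted(topo.chain_lengths()) == before
        assert _graph_is_paths(topo)
        assert "accept" in outcomes or "skip" in outcomes  # never crashes

    def test_sdb_preserves_length_multiset(self):
        state = _blend_state(seed=4, n_chains=6, N=6, n_singles=0, phi=0.2,
                             monodisperse=True)
        topo = state.config.topology
        before = sorted(topo.chain_lengths())
        n_acc = 0
        for _ in range(1500):
            out = attempt_sDB(state)
            n_acc += out == "accept"
            assert sorted(topo.chain_lengths()) == before
        assert _graph_is_paths(topo)

    def test_sdb_skips_in_dilute_tangent_system(self):
        # with tiny bond gaps and low density the double-bridge condition
        # is essentially never met
        state = _blend_state(seed=5, n_chains=4, N=6, n_singles=0,
                             phi=0.02, dl=0.02)
        outs = [attempt_sDB(state) for _ in range(300)]
        assert outs.count("skip") / len(outs) > 0.95

    @pytest.mark.parametrize("variant", [1, 2])
    def test_idex_single_chain_conserves_all_counts(self, variant):
        state = _blend_state(seed=6 + variant, phi=0.15)
        topo = state.config.topology
        nch, ns, nat = topo.n_chains, topo.n_singles, topo.n_sites
        acc = 0
        for _ in range(2500):
            out = attempt_IdEx(state, variant)
            acc += out == "accept"
            assert (topo.n_chains, topo.n_singles, topo.n_sites) == (nch, ns, nat)
        assert _graph_is_paths(topo)
        assert acc > 0

    def test_idex3_moves_length_between_chains(self):
        state = _blend_state(seed=9, phi=0.15)
        topo = state.config.topology
        nch, ns, nat = topo.n_chains, topo.n_singles, topo.n_sites
        total_before = sum(topo.chain_lengths())
        changed = False
        for _ in range(3000):
            before = sorted(topo.chain_lengths())
            out = attempt_IdEx(state, 3)
            assert (topo.n_chains, topo.n_singles) == (nch, ns)
            if out == "accept" and sorted(topo.chain_lengths()) != before:
                changed = True
        assert topo.n_sites == nat
        assert sum(topo.chain_lengths()) == total_before
        assert changed


class TestToyStationarity:
    def test_idex1_two_state_ratio(self):
        # collinear A-B bonded + single C at bond distance from B: the two
        # reachable states (chain AB + single C, chain BC + single A) are
        # symmetric, so occupation must be 1:1
        cell = SimulationCell([20.0] * 3)
        coords = np.array([[5.0, 5, 5], [6.0, 5, 5], [7.0, 5, 5]])
        topo = SpeciesTopology([[0, 1]], [2])
        cfg = Configuration(coords, topo, cell)
        spec = InteractionSpec(dl=0.05)
        state = MCSystem(cfg, spec, EnsembleSpec(), MoveSchedule(seed=10))
        counts = {0: 0, 2: 0}
        for _ in range(4000):
            attempt_IdEx(state, 1)
            counts[cfg.topology.singles[0]] += 1
        ratio = counts[0] / max(counts[2], 1)
        assert 0.85 < ratio < 1.18

    def test_monodisperse_mode_deactivates_length_changers(self):
        state = _blend_state(seed=11, monodisperse=True)
        assert attempt_sEB(state) == "skip"
        assert attempt_IdEx(state, 3) == "skip"
        from polypack.sampler import effective_probabilities

        probs = effective_probabilities(state)
        assert "seb" not in probs and "idex3" not in probs
        assert "inter_reptation" not in probs


class TestDecorrelation:
    def test_sieb_accelerates_end_to_end_decorrelation(self):
        # paired runs: with intramolecular rewiring on, the end-to-end
        # vector forgets its initial direction faster at equal sweeps
        def e2e_memory(use_sieb, seed):
            spec = InteractionSpec(dl=0.15)
            cfg = generate_dilute_system(
                1, 24, 0, SimulationCell([60.0] * 3), spec, seed=seed
            )
            probs = {"displacement": 0.5, "flip": 0.3}
            if use_sieb:
                probs["sieb"] = 0.2
            sched = MoveSchedule(probabilities=probs, seed=seed)
            state = MCSystem(cfg, spec, EnsembleSpec(), sched)
            chain = cfg.topology.chains[0]

            def e2e():
                c = cfg.topology.chains[0]
                d = cfg.coords[c[-1]] - cfg.coords[c[0]]
                return d / np.linalg.norm(d)

            v0 = e2e()
            dots = []
            for _ in range(30):
                run(state, 200)
                dots.append(float(np.dot(v0, e2e())))
            return np.mean(dots[-10:])

        wins = 0
        for seed in (21, 22, 23):
            if abs(e2e_memory(True, seed)) <= abs(e2e_memory(False, seed)) + 0.05:
                wins += 1
        assert wins >= 2
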