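"""Cluster detection/moves, volume moves and compression protocols."""

import math

import numpy as np
import pytest

from polypack.cell import SimulationCell
from polypack.clusters import detect_clusters, unwrap_cluster
from polypack.configuration import Configuration
from polypack.density import packing_density
from polypack.ensemble import EnsembleSpec
from polypack.generate import generate_dilute_system
from polypack.interactions import InteractionSpec, has_overlap
from polypack.moves_collective import (
    CompressionSchedule,
    attempt_cluster_move,
    attempt_volume_move,
    compress_to_jamming,
)
from polypack.schedule import MoveSchedule
from polypack.system import MCSystem
from polypack.topology import SpeciesTopology

from conftest import monomer_config, random_monomers


def _uf_oracle(config, linkage):
    """Brute-force all-pairs union-find clustering."""
    n = config.n_sites
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if config.distance(i, j) <= linkage:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestClusterDetection:
    def test_all_distant_sites_are_singletons(self):
        coords = np.array([[1, 1, 1], [5, 5, 5], [9, 1, 5]], dtype=float)
        cfg = monomer_config(coords, [12.0] * 3)
        cs = detect_clusters(cfg, 1.1)
        assert cs.n_clusters == 3
        assert all(len(m) == 1 for m in cs.members)

    def test_two_tangent_dimers(self):
        coords = np.array(
            [[2, 2, 2], [3, 2, 2], [8, 8, 8], [8, 9, 8]], dtype=float
        )
        cfg = monomer_config(coords, [12.0] * 3)
        cs = detect_clusters(cfg, 1.1)
        assert sorted(cs.sizes().tolist()) == [2, 2]

    def test_matches_brute_force_union_find(self, rng):
        for trial in range(25):
            n = int(rng.integers(8, 40))
            L = float(rng.uniform(4, 9))
            cfg = monomer_config(rng.uniform(0, L, size=(n, 3)), [L] * 3)
            link = float(rng.uniform(0.8, 1.6))
            ours = sorted(sorted(m.tolist()) for m in detect_clusters(cfg, link).members)
            assert ours == _uf_oracle(cfg, link)

    def test_label_condition_splits_touching_groups(self):
        coords = np.array([[2, 2, 2], [3, 2, 2], [4, 2, 2]], dtype=float)
        cfg = monomer_config(coords, [10.0] * 3)
        labels = np.array(["FCC", "FCC", "HCP"])
        cs = detect_clusters(cfg, 1.1, labels=labels)
        assert sorted(cs.sizes().tolist()) == [1, 2]

    def test_unwrap_across_periodic_boundary(self):
        coords = np.array([[0.2, 5, 5], [9.8, 5, 5]], dtype=float)
        cfg = monomer_config(coords, [10.0] * 3)
        cs = detect_clusters(cfg, 1.0)
        assert cs.n_clusters == 1
        pts = unwrap_cluster(cfg, cs.members[0], 1.0)
        assert np.linalg.norm(pts[1] - pts[0]) == pytest.approx(0.4, abs=1e-9)


def _sw_state(coords, L, seed=0, linkage=1.5, amplitude=1.0):
    cfg = monomer_config(coords, [L] * 3)
    spec = InteractionSpec(mode="SW", eps_sw=1.0, sigma2=1.5)
    sched = MoveSchedule(
        seed=seed, cluster_linkage=linkage, cluster_amplitude=amplitude
    )
    return MCSystem(cfg, spec, EnsembleSpec(), sched)


class TestClusterMoves:
    def test_single_cluster_deactivates_move(self):
        state = _sw_state(np.array([[5.0, 5, 5], [6.0, 5, 5]]), 12.0)
        assert attempt_cluster_move(state, "CluDis") == "skip"

    def test_rigid_body_preserves_internal_geometry(self):
        coords = np.array(
            [[3, 3, 3], [4, 3, 3], [3.5, 3.9, 3], [9, 9, 9]], dtype=float
        )
        state = _sw_state(coords, 14.0, seed=1, amplitude=2.0)
        cfg = state.config
        d01, d02 = cfg.distance(0, 1), cfg.distance(0, 2)
        accepted = 0
        for kind in ("CluDis", "CluRot") * 120:
            if attempt_cluster_move(state, kind) == "accept":
                accepted += 1
            assert cfg.distance(0, 1) == pytest.approx(d01, abs=1e-10)
            assert cfg.distance(0, 2) == pytest.approx(d02, abs=1e-10)
        assert accepted > 0

    def test_accepted_moves_never_merge_clusters(self):
        # reject-on-merge: after every accepted move the two clusters are
        # still farther apart than the linkage distance
        coords = np.array(
            [[4, 5, 5], [5, 5, 5], [8.0, 5, 5], [9.0, 5, 5]], dtype=float
        )
        state = _sw_state(coords, 14.0, seed=2, linkage=1.4, amplitude=1.5)
        cfg = state.config
        for _ in range(400):
            attempt_cluster_move(state, "CluDis")
            cs = detect_clusters(cfg, 1.4)
            assert cs.n_clusters == 2

    def test_aggregation_faster_with_cluster_moves(self):
        # two SW dimers at low density meet sooner when cluster moves are
        # active (paired-seed comparison)
        def steps_to_merge(use_cluster, seed):
            rng = np.random.default_rng(seed)
            coords = np.array(
                [[3, 3, 3], [4, 3, 3], [10, 10, 10], [10, 11, 10]],
                dtype=float,
            )
            state = _sw_state(coords, 15.0, seed=seed, linkage=1.5,
                              amplitude=2.5)
            from polypack.moves_local import attempt_monomer_displacement

            for step in range(4000):
                if use_cluster and step % 2 == 0:
                    attempt_cluster_move(
                        state, "CluDis" if rng.uniform() < 0.7 else "CluRot"
                    )
                else:
                    attempt_monomer_displacement(state)
                if detect_clusters(state.config, 1.5).n_clusters == 1:
                    return step
            return 4000

        wins = 0
        for seed in (31, 32, 33):
            if steps_to_merge(True, seed) <= steps_to_merge(False, seed):
                wins += 1
        assert wins >= 2


class TestVolumeMoves:
    def test_expansion_always_accepted_at_zero_pressure(self):
        cfg = random_monomers(5, 0.1, seed=3)
        state = MCSystem(cfg, InteractionSpec(), EnsembleSpec(),
                         MoveSchedule(seed=4))
        v0 = cfg.cell.volume
        outs = set()
        for _ in range(50):
            # force expansions: P=0 makes -P dV + N ln(V'/V) >= 0
            out = attempt_volume_move(state, pressure=0.0, amplitude=0.05)
            outs.add(out)
            if cfg.cell.volume > v0:
                break
        assert "accept" in outs

    def test_compression_into_overlap_rejected(self):
        coords = np.array([[0.5, 0.5, 0.5], [1.52, 0.5, 0.5]])
        cfg = monomer_config(coords, [3.05, 3.05, 3.05])
        state = MCSystem(cfg, InteractionSpec(), EnsembleSpec(),
                         MoveSchedule(seed=5))
        for _ in range(100):
            out = attempt_volume_move(
                state, pressure=50.0, shrink_only=True, amplitude=0.2
            )
            if out == "accept":
                assert not has_overlap(cfg, spec=state.spec, grids=state.grids)
        # pair distance can never drop below sigma
        assert cfg.distance(0, 1) >= 1.0 - 1e-9

    def test_anisotropic_scaling_respects_confined_dims(self):
        from polypack.cell import Walls

        cell = SimulationCell([8.0, 8.0, 6.0], confinement=Walls((2,)))
        coords = np.array([[4.0, 4.0, 3.0]])
        cfg = Configuration(coords, SpeciesTopology([], [0]), cell)
        state = MCSystem(cfg, InteractionSpec(), EnsembleSpec(),
                         MoveSchedule(seed=6))
        for _ in range(30):
            attempt_volume_move(state, pressure=1.0, isotropic=False,
                                amplitude=0.1)
        assert cfg.cell.lengths[2] == pytest.approx(6.0)


class TestCompression:
    def test_single_sphere_reaches_self_image_limit(self):
        # one sphere in a periodic box can shrink until L = sigma,
        # phi -> pi/6 (simple-cubic self-image limit)
        cfg = monomer_config([[1.0, 1.0, 1.0]], [3.0, 3.0, 3.0])
        state = MCSystem(cfg, InteractionSpec(), EnsembleSpec(),
                         MoveSchedule(seed=7))
        sched = CompressionSchedule(
            sweeps_per_cycle=1, initial_amplitude=0.05, decay=0.8,
            tolerance=1e-9, window=10, max_cycles=4000,
        )
        phis, _ = compress_to_jamming(state, sched)
        assert phis[-1] == pytest.approx(math.pi / 6.0, rel=0.01)

    def test_volume_monotone_and_bonds_survive_shrink(self):
        spec = InteractionSpec(dl=0.15)
        cfg = generate_dilute_system(
            2, 5, 3, SimulationCell([12.0] * 3), spec, seed=8
        )
        state = MCSystem(cfg, spec, EnsembleSpec(),
                         MoveSchedule(l_disp=0.2, seed=9))
        sched = CompressionSchedule(
            sweeps_per_cycle=2, initial_amplitude=0.01, window=10,
            max_cycles=300,
        )
        vols = [cfg.cell.volume]
        phis, _ = compress_to_jamming(state, sched)
        assert packing_density(cfg) > phis[0]
        assert np.all(np.diff(phis) >= -1e-12)  # phi never decreases
        assert not has_overlap(cfg, spec=spec, grids=state.grids)
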