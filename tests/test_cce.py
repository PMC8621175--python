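"""Crystal-similarity descriptor: Voronoi shells, norms, labels, order."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from polypack.cell import SimulationCell
from polypack.cce import (
    EPS_THRES_DEFAULT,
    PENALTY_NORM,
    cce_norms,
    get_catalog,
    label_sites,
    order_summary,
    site_norm,
    voronoi_cell_stats,
    voronoi_neighbors,
    voronoi_shells,
)
from polypack.configuration import Configuration
from polypack.errors import ConfigError, GenerationError
from polypack.lattices import generate_ideal_lattice
from polypack.topology import SpeciesTopology

FIXTURES_3D = [("FCC", 3), ("HCP", (3, 2, 2)), ("BCC", 3), ("HEX", (3, 2, 3))]
FIXTURES_2D = [("TRI", 4), ("SQU", 4), ("HON", (2, 3))]


def _center_site(name):
    return 0  # lattice generators put a basis atom at the origin


class TestVoronoiNeighbors:
    @pytest.mark.parametrize(
        "name,reps,expected",
        [
            ("FCC", 3, 12),
            ("HCP", (3, 2, 2), 12),
            ("BCC", 3, 14),
            ("HEX", (3, 2, 3), 8),
            ("TRI", 4, 6),
            ("SQU", 4, 4),
            ("HON", (2, 3), 3),
        ],
    )
    def test_ideal_lattice_coordination(self, name, reps, expected):
        cfg = generate_ideal_lattice(name, reps)
        shells = voronoi_shells(cfg)
        assert all(s.n_vor == expected for s in shells)

    def test_bcc_first_shell_used_by_descriptor(self):
        # 14 Voronoi faces; the 8 nearest (cube corners) come first
        cfg = generate_ideal_lattice("BCC", 3)
        shell = voronoi_shells(cfg)[0]
        assert shell.n_vor == 14
        d = shell.distances
        assert np.allclose(d[:8], 1.0, atol=1e-6)
        assert np.all(d[8:] > 1.1)

    def test_single_site_api(self):
        cfg = generate_ideal_lattice("FCC", 3)
        ids, n_vor = voronoi_neighbors(cfg, 5)
        assert n_vor == 12 and len(ids) == 12

    def test_cell_stats_on_fcc(self):
        cfg = generate_ideal_lattice("FCC", 3)
        stats = voronoi_cell_stats(cfg)
        # rhombic dodecahedron: volume = cell volume per site
        per_site = cfg.cell.volume / cfg.n_sites
        assert np.nanmean(stats["volume"]) == pytest.approx(per_site, rel=1e-3)
        assert np.all(stats["faces"] == 12)


class TestNorm:
    @pytest.mark.parametrize("name,reps", FIXTURES_3D + FIXTURES_2D)
    def test_own_crystal_norm_vanishes(self, name, reps):
        cfg = generate_ideal_lattice(name, reps)
        shells = voronoi_shells(cfg)
        crystal = next(
            c for c in get_catalog(cfg.dim) if c.name == name
        )
        eps = site_norm(shells[_center_site(name)].vectors, crystal)
        assert eps < 0.05

    @pytest.mark.parametrize("name", ["FIV", "PEN"])
    def test_fivefold_cluster_center(self, name):
        cfg = generate_ideal_lattice(name)
        shells = voronoi_shells(cfg)
        crystal = next(c for c in get_catalog(cfg.dim) if c.name == name)
        assert site_norm(shells[0].vectors, crystal) < 0.05

    def test_mesh_refinement_never_increases_norm(self):
        cfg = generate_ideal_lattice("FCC", 3, noise=0.03, seed=1)
        shells = voronoi_shells(cfg)
        fcc = next(c for c in get_catalog(3) if c.name == "FCC")
        coarse = site_norm(
            shells[0].vectors, fcc, phi_step=np.deg2rad(20), refine=False
        )
        fine = site_norm(
            shells[0].vectors, fcc, phi_step=np.deg2rad(10), refine=False
        )
        refined = site_norm(shells[0].vectors, fcc, phi_step=np.deg2rad(20))
        assert fine <= coarse + 1e-12
        assert refined <= fine + 1e-9

    def test_penalty_when_coordination_deficient(self):
        vecs = np.array(
            [[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]]
        )
        fcc = next(c for c in get_catalog(3) if c.name == "FCC")
        assert site_norm(vecs, fcc) == PENALTY_NORM >= 1.0

    def test_unknown_crystal_rejected(self):
        with pytest.raises(ConfigError):
            get_catalog(3, ["XYZ"])
        with pytest.raises(ConfigError):
            get_catalog(2, ["FCC"])  # wrong dimensionality

    def test_rotation_invariance(self):
        # rigidly rotating a configuration may change epsilon only within
        # the orientation-mesh tolerance
        cfg = generate_ideal_lattice("FIV", noise=0.02, seed=3)
        shells = voronoi_shells(cfg)
        fiv = next(c for c in get_catalog(3) if c.name == "FIV")
        eps0 = site_norm(shells[0].vectors, fiv)
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        rot = Configuration(
            (cfg.coords - cfg.cell.center) @ R.T + cfg.cell.center,
            cfg.topology.copy(),
            cfg.cell,
        )
        eps1 = site_norm(voronoi_shells(rot)[0].vectors, fiv)
        assert abs(eps1 - eps0) < 0.02


class TestDiscrimination:
    @pytest.mark.parametrize("name,reps", FIXTURES_3D)
    def test_cross_norms_exceed_threshold_3d(self, name, reps):
        cfg = generate_ideal_lattice(name, reps)
        shells = voronoi_shells(cfg)
        for crystal in get_catalog(3):
            if crystal.name == name:
                continue
            eps = site_norm(shells[0].vectors, crystal)
            assert eps > EPS_THRES_DEFAULT, (name, crystal.name, eps)

    @pytest.mark.parametrize("name,reps", FIXTURES_2D)
    def test_cross_norms_exceed_threshold_2d(self, name, reps):
        cfg = generate_ideal_lattice(name, reps)
        shells = voronoi_shells(cfg)
        for crystal in get_catalog(2):
            if crystal.name == name:
                continue
            eps = site_norm(shells[0].vectors, crystal)
            assert eps > EPS_THRES_DEFAULT, (name, crystal.name, eps)

    def test_fivefold_discriminates_close_packed(self):
        cfg = generate_ideal_lattice("FIV")
        shells = voronoi_shells(cfg)
        for crystal in get_catalog(3):
            if crystal.name == "FIV":
                continue
            assert site_norm(shells[0].vectors, crystal) > EPS_THRES_DEFAULT


class TestLabeling:
    def test_noise_robustness_fcc(self):
        # 0.05 sigma Gaussian jitter keeps >= 95% of sites FCC-labeled
        cfg = generate_ideal_lattice("FCC", 4, noise=0.05, seed=2)
        labels = label_sites(cce_norms(cfg))
        assert np.mean(labels == "FCC") >= 0.95

    def test_ideal_hcp_fully_labeled(self):
        cfg = generate_ideal_lattice("HCP", (3, 2, 2))
        labels = label_sites(cce_norms(cfg))
        assert np.all(labels == "HCP")

    def test_zero_threshold_labels_all_amorphous(self):
        cfg = generate_ideal_lattice("FCC", 3)
        res = cce_norms(cfg, crystals=["FCC", "HCP"])
        assert np.all(label_sites(res, eps_thres=0.0) == "AMO")

    def test_on_the_fly_matches_full_labels(self):
        cfg = generate_ideal_lattice("FCC", 3, noise=0.04, seed=5)
        full = label_sites(cce_norms(cfg, crystals=["FCC", "HCP", "FIV"]))
        otf = label_sites(
            cce_norms(cfg, crystals=["FCC", "HCP", "FIV"], on_the_fly=True)
        )
        assert np.array_equal(full, otf)

    def test_2d_triangular_fully_labeled(self):
        cfg = generate_ideal_lattice("TRI", 4)
        labels = label_sites(cce_norms(cfg))
        assert np.all(labels == "TRI")


class TestOrderSummary:
    def test_perfect_fcc_crystallinity(self):
        cfg = generate_ideal_lattice("FCC", 3)
        labels = label_sites(cce_norms(cfg, crystals=["FCC", "HCP", "FIV"]))
        s = order_summary(labels, cfg, linkage=1.1)
        assert s.tau_c == pytest.approx(1.0)
        assert s.s_fiv == 0.0
        assert sum(s.fractions.values()) == pytest.approx(1.0)

    def test_two_separated_grains_give_two_ordered_clusters(self):
        # two ideal FCC blocks far apart inside a large open box
        block = generate_ideal_lattice("FCC", 3).coords
        shift = np.array([block[:, 0].max() + 8.0, 0.0, 0.0])
        pts = np.vstack([block, block + shift]) + 4.0
        L = pts.max() + 8.0
        cell = SimulationCell([L] * 3, periodic=[False] * 3)
        cfg = Configuration(pts, SpeciesTopology([], range(len(pts))), cell)
        labels = label_sites(cce_norms(cfg, crystals=["FCC", "HCP", "FIV"]))
        from polypack.clusters import detect_clusters

        cs = detect_clusters(cfg, 1.1, labels=labels)
        fcc_clusters = [
            m for m in cs.members if labels[m[0]] == "FCC" and len(m) >= 12
        ]
        assert len(fcc_clusters) == 2

    def test_fractions_sum_to_one_with_amo(self):
        rng = np.random.default_rng(0)
        L = 8.0
        pts = rng.uniform(0, L, size=(60, 3))
        cfg = Configuration(
            pts, SpeciesTopology([], range(60)), SimulationCell([L] * 3)
        )
        labels = label_sites(
            cce_norms(cfg, crystals=["FCC", "HCP", "FIV"], on_the_fly=True)
        )
        s = order_summary(labels, cfg, include_voronoi=False)
        assert sum(s.fractions.values()) == pytest.approx(1.0)


class TestLatticeGenerators:
    def test_fcc_supercell_count(self):
        cfg = generate_ideal_lattice("FCC", 4)
        assert cfg.n_sites == 4 * 64

    def test_zero_noise_exact_neighbor_distances(self):
        for name, reps in FIXTURES_3D:
            cfg = generate_ideal_lattice(name, reps, spacing=1.0)
            d = voronoi_shells(cfg)[0].distances
            assert d.min() == pytest.approx(1.0, abs=1e-6)

    def test_hcp_ideal_axial_ratio_uniform_first_shell(self):
        cfg = generate_ideal_lattice("HCP", (3, 2, 2))
        d = voronoi_shells(cfg)[0].distances
        assert np.allclose(d, 1.0, atol=1e-6)

    def test_too_small_supercell_rejected(self):
        with pytest.raises(GenerationError):
            generate_ideal_lattice("FCC", 1)

    def test_jitter_determinism(self):
        a = generate_ideal_lattice("BCC", 3, noise=0.03, seed=9).coords
        b = generate_ideal_lattice("BCC", 3, noise=0.03, seed=9).coords
        assert np.array_equal(a, b)
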