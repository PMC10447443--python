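"""Hydrogen bonds, dihedral histograms, alignment, density maps, G(r)/D(r)."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shiftsel.core import (GeometryError, LocalEnvironment,
                           MolecularTopology, PeriodicCell, Snapshot)
from shiftsel.structure import (DensityMapSpec, HBondCriteria,
                                align_environments, curve_residual,
                                density_difference_map, density_map,
                                detect_hbond, dihedral_histogram,
                                hbond_census, radial_distribution)
from shiftsel.synthetic import (generate_packing, set_dihedral, toy_template,
                                trivial_topology)
from shiftsel.environments import extract_all_environments


# ---------------------------------------------------------------------------
# Hydrogen bonds: constructed donor/acceptor geometries
# ---------------------------------------------------------------------------

_HB_TOPO = MolecularTopology(
    site_labels=("O1", "H1", "C1", "N1"),
    elements={"O1": "O", "H1": "H", "C1": "C", "N1": "N"},
    bonds=frozenset({("O1", "H1"), ("O1", "C1"), ("C1", "N1")}),
    hbond_donor=("O1", "H1"),
    hbond_acceptors=(("N1", "N"),),
)


def _hb_env(distance, angle_deg, acceptor_element="N"):
    """Two molecules: a donor O-H and an acceptor X placed at the requested
    H...X distance and O-H-X angle."""
    h = np.zeros(3)
    o = np.array([-0.97, 0.0, 0.0])  # O-H along -x, so H->O is -x
    theta = np.radians(180.0 - angle_deg)
    x = h + distance * np.array([np.cos(theta), np.sin(theta), 0.0])
    far = np.array([50.0, 50.0, 50.0])
    central = np.array([o, h, o + [0, 1.4, 0], far])
    if acceptor_element == "N":
        other = np.array([far + 5, far + 6, far + 7, x])
    coords = np.stack([central, other])
    return LocalEnvironment(0, (0, 1), coords, 7.0, (0, 0), _HB_TOPO)


class TestDetectHBond:
    def test_within_both_criteria_bonds(self):
        hb = detect_hbond(_hb_env(2.4, 150.0))
        assert hb is not None
        assert hb.acceptor_site_label == "N1"
        assert hb.distance == pytest.approx(2.4)
        assert hb.angle == pytest.approx(150.0)

    def test_distance_failure(self):
        assert detect_hbond(_hb_env(2.6, 170.0)) is None

    def test_angle_failure(self):
        assert detect_hbond(_hb_env(2.4, 120.0)) is None

    def test_tie_broken_by_shortest_distance(self):
        env = _hb_env(2.4, 150.0)
        # add a second, closer qualifying acceptor on member 1 (site N1 of a
        # third molecule placed via new coordinates array)
        h = env.coordinates[0, 1]
        oh = env.coordinates[0, 0] - h
        closer = h - 2.2 * oh / np.linalg.norm(oh)
        extra = np.array([[60.0, 60, 60], [61.0, 60, 60], [62.0, 60, 60],
                          closer])
        coords = np.concatenate([env.coordinates, extra[None]], axis=0)
        env2 = LocalEnvironment(0, (0, 1, 2), coords, 7.0, (0, 0), _HB_TOPO)
        hb = detect_hbond(env2)
        assert hb.distance == pytest.approx(2.2)
        assert hb.acceptor_molecule_id == 2

    def test_missing_donor_raises(self):
        topo = trivial_topology()  # declares no donor
        env = LocalEnvironment(0, (0,), np.zeros((1, 3, 3)), 7.0, (0, 0), topo)
        from shiftsel.core import TopologyError
        with pytest.raises(TopologyError):
            detect_hbond(env)


class TestHBondCensus:
    def test_all_bonded_single_category(self):
        envs = [_hb_env(2.3, 160.0) for _ in range(5)]
        census = hbond_census(envs)
        assert census == {"N1": 1.0}

    def test_none_bonded(self):
        envs = [_hb_env(2.8, 160.0) for _ in range(4)]
        assert hbond_census(envs) == {"none": 1.0}

    def test_planted_mixture_recovered(self):
        """30/70 planted H-bond mixture recovered exactly (generation is
        consistency-checked, so recovery is exact, not just binomial)."""
        snap, manifest = generate_packing(n_molecules=20, cell_side=26.0,
                                          hbond_fraction=0.3, seed=21)
        envs = extract_all_environments([snap])
        census = hbond_census(envs)
        assert sum(census.values()) == pytest.approx(1.0, abs=1e-12)
        assert 1.0 - census.get("none", 0.0) == pytest.approx(
            manifest["hbond_planted"].mean())


# ---------------------------------------------------------------------------
# Dihedral histograms
# ---------------------------------------------------------------------------

def _conformer_env(angle):
    topo, base = toy_template()
    coords = set_dihedral(base, topo, "backbone", angle)
    return LocalEnvironment(0, (0,), coords[None], 7.0, (0, 0), topo)


class TestDihedralHistogram:
    def test_single_conformer_single_bin(self):
        envs = [_conformer_env(65.0)] * 7
        counts, edges = dihedral_histogram(envs, "backbone", bins=36)
        assert counts.sum() == 7
        occupied = np.nonzero(counts)[0]
        assert len(occupied) == 1
        assert edges[occupied[0]] <= 65.0 < edges[occupied[0] + 1]

    def test_symmetric_mixture_is_mirror_symmetric(self):
        envs = [_conformer_env(a) for a in (90.0, -90.0) for _ in range(3)]
        counts, _ = dihedral_histogram(envs, "backbone", bins=36)
        assert np.array_equal(counts, counts[::-1])

    def test_wraparound_at_180(self):
        envs = [_conformer_env(180.0)]
        counts, _ = dihedral_histogram(envs, "backbone", bins=36)
        assert counts.sum() == 1
        assert counts[-1] == 1  # 180 lands in the topmost bin

    def test_undefined_name_raises(self):
        from shiftsel.core import TopologyError
        with pytest.raises(TopologyError):
            dihedral_histogram([_conformer_env(0.0)], "nonexistent")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

ALIGN_SITES = ("H1", "O1", "C2")


def _toy_env(coords, topo):
    return LocalEnvironment(0, (0,), coords[None], 7.0, (0, 0), topo)


class TestAlignment:
    def test_rigid_copy_aligns_to_zero_rmsd(self):
        topo, base = toy_template()
        rot = Rotation.from_euler("xyz", [20, -40, 75], degrees=True)
        moved = rot.apply(base) + np.array([3.0, -1.0, 2.5])
        aligned, rmsds = align_environments(
            [_toy_env(base, topo), _toy_env(moved, topo)], ALIGN_SITES)
        assert rmsds[0] == pytest.approx(0.0, abs=1e-12)
        assert rmsds[1] == pytest.approx(0.0, abs=1e-7)
        # all atoms (not only alignment atoms) recover their positions
        assert np.allclose(aligned[1], base, atol=1e-7)

    def test_two_point_alignment_rejected(self):
        topo, base = toy_template()
        with pytest.raises(GeometryError):
            align_environments([_toy_env(base, topo)], ("H1", "O1"))

    def test_collinear_sites_rejected(self):
        topo = MolecularTopology(
            ("A1", "B1", "C1"), {s: "C" for s in ("A1", "B1", "C1")},
            frozenset({("A1", "B1"), ("B1", "C1")}))
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        env = LocalEnvironment(0, (0,), coords[None], 7.0, (0, 0), topo)
        with pytest.raises(GeometryError):
            align_environments([env], ("A1", "B1", "C1"))

    def test_beats_random_rotations(self):
        """Kabsch RMSD is at most the best of 1000 random proper rotations
        (each with its optimal translation)."""
        topo, base = toy_template()
        rng = np.random.default_rng(17)
        ref_pts = base[[topo.index(s) for s in ALIGN_SITES]]
        for trial in range(5):
            noisy = base + rng.normal(0, 0.8, base.shape)
            _, rmsds = align_environments(
                [_toy_env(base, topo), _toy_env(noisy, topo)], ALIGN_SITES)
            pts = noisy[[topo.index(s) for s in ALIGN_SITES]]
            a = ref_pts - ref_pts.mean(axis=0)
            b = pts - pts.mean(axis=0)
            rots = Rotation.from_quat(rng.normal(size=(1000, 4)))
            best = min(np.sqrt(np.mean(np.sum((a - r.apply(b)) ** 2, axis=1)))
                       for r in rots)
            assert rmsds[1] <= best + 1e-12

    def test_rmsd_invariant_to_prerotation(self):
        topo, base = toy_template()
        rng = np.random.default_rng(23)
        noisy = base + rng.normal(0, 0.5, base.shape)
        _, r1 = align_environments(
            [_toy_env(base, topo), _toy_env(noisy, topo)], ALIGN_SITES)
        rot = Rotation.from_euler("zxy", [11, 62, -140], degrees=True)
        _, r2 = align_environments(
            [_toy_env(base, topo), _toy_env(rot.apply(noisy) + 5.0, topo)],
            ALIGN_SITES)
        assert r2[1] == pytest.approx(r1[1], abs=1e-9)


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

class TestDensityMap:
    def test_atom_on_grid_node_gives_exactly_one(self):
        topo, base = toy_template()
        spec = DensityMapSpec()
        center = np.array([0.0, 0.0, 0.0])
        # place the single N atom exactly on the node at center + (0.4, 0, 0)
        coords = base - base[topo.index("N1")] + center + [0.4, 0.0, 0.0]
        vals, _ = density_map([coords[None]], topo.element_array(), "N",
                              spec, center=center)
        node = (15 + 1, 15, 15)  # 31-point axis: index 15 is the center
        assert vals[node] == pytest.approx(1.0, abs=1e-12)
        assert vals.max() == pytest.approx(1.0, abs=1e-12)

    def test_absent_element_gives_zero_map(self):
        topo, base = toy_template()
        vals, _ = density_map([base[None]], topo.element_array(), "Cl",
                              DensityMapSpec(), center=np.zeros(3))
        assert np.all(vals == 0.0)

    def test_repeated_environment_still_one(self):
        """Mean of identical unit Gaussians stays 1 at the shared position."""
        topo, base = toy_template()
        center = np.zeros(3)
        coords = base - base[topo.index("N1")] + center
        vals, _ = density_map([coords[None], coords[None].copy()],
                              topo.element_array(), "N", DensityMapSpec(),
                              center=center)
        assert vals[15, 15, 15] == pytest.approx(1.0, abs=1e-12)

    def test_grid_spacing(self):
        assert DensityMapSpec().spacing == pytest.approx(0.4)

    def test_single_atom_maps_bounded_by_one(self):
        topo, base = toy_template()
        rng = np.random.default_rng(6)
        envs = [(base + rng.normal(0, 1, 3))[None] for _ in range(4)]
        vals, _ = density_map(envs, topo.element_array(), "N",
                              DensityMapSpec(), center=np.zeros(3))
        assert vals.max() <= 1.0 + 1e-9  # one N atom per environment

    def test_linearity_over_environment_sets(self):
        topo, base = toy_template()
        rng = np.random.default_rng(8)
        a = [(base + rng.normal(0, 1, 3))[None] for _ in range(3)]
        b = [(base + rng.normal(0, 1, 3))[None] for _ in range(5)]
        spec = DensityMapSpec(grid_points_per_side=11, cube_side=8.0)
        c = np.zeros(3)
        els = topo.element_array()
        va, _ = density_map(a, els, "O", spec, center=c)
        vb, _ = density_map(b, els, "O", spec, center=c)
        vab, _ = density_map(a + b, els, "O", spec, center=c)
        want = (3 * va + 5 * vb) / 8
        assert np.allclose(vab, want, atol=1e-12)
        # permutation invariance over environments
        vba, _ = density_map(b + a, els, "O", spec, center=c)
        assert np.allclose(vab, vba)

    def test_difference_map(self):
        x = np.zeros((5, 5, 5))
        y = np.zeros((5, 5, 5))
        y[2, 2, 2] = 1.0
        diff = density_difference_map(y, x)
        assert diff[2, 2, 2] == 1.0
        assert np.all(density_difference_map(x, x) == 0.0)
        with pytest.raises(ValueError):
            density_difference_map(x, np.zeros((4, 4, 4)))


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

def _monatomic_topology():
    return MolecularTopology(("X1",), {"X1": "C"}, frozenset())


class TestRadialDistribution:
    def test_ideal_gas_tends_to_one(self):
        """Uniform random configuration: g(r) -> 1 at large r within 3
        sampling standard deviations."""
        topo = _monatomic_topology()
        cell = PeriodicCell.cubic(24.0)
        rng = np.random.default_rng(31)
        snaps = [Snapshot(cell, topo, rng.uniform(0, 24, (400, 1, 3)),
                          np.arange(400), (0, f)) for f in range(4)]
        rdf = radial_distribution(snaps, r_max=10.0, dr=0.25)
        tail = rdf.r > 5.0
        g = rdf.partials[("C", "C")][tail]
        # expected counts per bin give the sampling sigma
        n_pairs = 4 * 400 * 399 / 24.0 ** 3
        shell = 4 * np.pi * rdf.r[tail] ** 2 * 0.25
        sigma = 1.0 / np.sqrt(n_pairs * shell)
        assert np.all(np.abs(g - 1.0) < 3.5 * sigma + 0.02)

    def test_isolated_pair_peak(self):
        topo = _monatomic_topology()
        cell = PeriodicCell.cubic(40.0)
        pos = np.array([[[10.0, 10, 10]], [[13.0, 10, 10]]])
        snap = Snapshot(cell, topo, pos, np.array([0, 1]))
        rdf = radial_distribution([snap], r_max=8.0, dr=0.2)
        assert rdf.r[np.argmax(rdf.g_total)] == pytest.approx(3.1, abs=0.11)

    def test_cubic_lattice_shell_distances(self):
        """Peaks at a, a*sqrt(2), a*sqrt(3) for a simple cubic lattice."""
        topo = _monatomic_topology()
        a = 3.0
        n = 6
        grid = np.array([[i, j, k] for i in range(n) for j in range(n)
                         for k in range(n)], dtype=float) * a
        cell = PeriodicCell.cubic(n * a)
        snap = Snapshot(cell, topo, grid[:, None, :], np.arange(n ** 3))
        rdf = radial_distribution([snap], r_max=0.45 * n * a, dr=0.05)
        occupied = rdf.r[rdf.g_total > 1e-9]
        expected = {a * np.sqrt(m) for m in (1, 2, 3, 4, 5, 6, 8)}
        for r_occ in occupied:
            assert any(abs(r_occ - e) <= 0.051 for e in expected)
        for e in sorted(expected)[:3]:
            assert any(abs(r_occ - e) <= 0.051 for r_occ in occupied)

    def test_total_is_weighted_sum_of_partials(self, small_trajectory):
        snaps, *_ = small_trajectory
        rdf = radial_distribution(snaps[:2], r_max=9.0, dr=0.1)
        recomposed = sum(rdf.weights[p] * rdf.partials[p] for p in rdf.partials)
        assert np.allclose(rdf.g_total, recomposed)
        assert sum(rdf.weights.values()) == pytest.approx(1.0)

    def test_r_max_exceeding_half_cell_raises(self):
        topo = _monatomic_topology()
        cell = PeriodicCell.cubic(10.0)
        snap = Snapshot(cell, topo, np.zeros((1, 1, 3)), np.array([0]))
        with pytest.raises(GeometryError):
            radial_distribution([snap], r_max=6.0)


class TestCurveResidual:
    def test_identical_curves_zero(self):
        r = np.linspace(0, 10, 101)
        y = np.sin(r)
        res = curve_residual((r, y), (r, y))
        assert res.rmse == pytest.approx(0.0, abs=1e-14)
        assert res.rmse_subrange == pytest.approx(0.0, abs=1e-14)

    def test_constant_offset(self):
        r = np.linspace(0, 12, 200)
        res = curve_residual((r, np.cos(r)), (r, np.cos(r) + 0.7))
        assert res.rmse == pytest.approx(0.7)
        assert res.rmse_subrange == pytest.approx(0.7)

    def test_random_curves_match_direct_formula(self):
        rng = np.random.default_rng(41)
        r = np.linspace(0, 15, 300)
        y1, y2 = rng.normal(size=(2, 300))
        res = curve_residual((r, y1), (r, y2))
        assert res.rmse == pytest.approx(np.sqrt(np.mean((y2 - y1) ** 2)))
        sub = (r >= 3) & (r <= 10)
        assert res.rmse_subrange == pytest.approx(
            np.sqrt(np.mean((y2 - y1)[sub] ** 2)))

    def test_disjoint_supports_raise(self):
        with pytest.raises(ValueError):
            curve_residual((np.array([0.0, 1]), np.array([1.0, 1])),
                           (np.array([5.0, 6]), np.array([1.0, 1])))
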