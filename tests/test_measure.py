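import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molkit import (MolkitError, PeriodicBox, RigidTransform, center_of_geometry,
                    center_of_mass, fit_transform, kabsch, radius_of_gyration,
                    rmsd, sasa)


class TestCenters:
    def test_equal_masses(self):
        coords = np.array([[0, 0, 0], [2, 0, 0]], float)
        assert np.allclose(center_of_mass(coords, masses=[1, 1]), [1, 0, 0])

    def test_unequal_masses(self):
        coords = np.array([[0, 0, 0], [4, 0, 0]], float)
        assert np.allclose(center_of_mass(coords, masses=[1, 3]), [3, 0, 0])

    def test_zero_total_mass_rejected(self):
        with pytest.raises(MolkitError):
            center_of_mass(np.zeros((2, 3)), masses=[0, 0])

    def test_pbc_without_box_rejected(self):
        with pytest.raises(MolkitError):
            center_of_mass(np.zeros((2, 3)), masses=[1, 1], pbc=True)

    def test_pbc_cluster_across_boundary(self):
        """Equal masses at x=0.5 and x=9.5 in a 10 nm box: COM at x==0 mod 10.

        Oracle: brute-force minimization of the wrapped squared distance sum
        over a fine grid of candidate centers.
        """
        box = PeriodicBox.cubic(10.0)
        coords = np.array([[0.5, 5, 5], [9.5, 5, 5]], float)
        com = center_of_mass(coords, masses=[1, 1], pbc=True, box=box)
        assert min(abs(com[0] - 0.0), abs(com[0] - 10.0)) < 1e-9

        grid = np.linspace(0, 10, 2001, endpoint=False)
        cost = [np.sum(np.minimum(np.abs(coords[:, 0] - c),
                                  10 - np.abs(coords[:, 0] - c)) ** 2)
                for c in grid]
        best = grid[int(np.argmin(cost))]
        dx = abs(com[0] - best)
        assert min(dx, 10 - dx) < 0.01

    def test_pbc_com_invariant_under_whole_box_shifts(self):
        rng = np.random.default_rng(3)
        box = PeriodicBox.from_lengths_angles(4, 5, 6, 90, 90, 80)
        coords = box.to_cartesian(rng.uniform(0.4, 0.6, size=(20, 3)))
        masses = rng.uniform(1, 16, size=20)
        ref = center_of_mass(coords, masses=masses, pbc=True, box=box)
        shifted = coords.copy()
        shifted[::3] += box.matrix[0] + 2 * box.matrix[2]
        com = center_of_mass(shifted, masses=masses, pbc=True, box=box)
        delta = box.to_fractional(com - ref)
        assert np.allclose(delta - np.round(delta), 0, atol=1e-9)

    def test_cog_is_plain_mean(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(30, 3))
        assert np.allclose(center_of_geometry(coords), coords.mean(axis=0))


class TestRmsd:
    def test_identical_is_zero(self, rng):
        coords = rng.normal(size=(10, 3))
        assert rmsd(coords, coords) == 0.0

    def test_closed_form_pair(self):
        a = np.array([[0, 0, 0], [1, 0, 0]], float)
        b = np.array([[0, 0, 0], [1, 1, 0]], float)
        assert math.isclose(rmsd(a, b), math.sqrt(0.5), rel_tol=1e-12)

    def test_translation_invariance(self, rng):
        a, b = rng.normal(size=(2, 15, 3))
        v = np.array([1.0, -2.0, 0.5])
        assert math.isclose(rmsd(a, b), rmsd(a + v, b + v), rel_tol=1e-12)

    def test_size_mismatch_rejected(self):
        with pytest.raises(MolkitError):
            rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestKabsch:
    def test_self_fit_is_identity(self, rng):
        coords = rng.normal(size=(20, 3))
        t = kabsch(coords, coords)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-10)
        assert np.allclose(t.translation, 0, atol=1e-10)

    def test_recovers_constructed_transform(self, rng):
        coords = rng.normal(size=(25, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ R.T + np.array([1.0, 2.0, 3.0])
        t = kabsch(moved, coords)
        assert rmsd(t.apply(moved), coords) < 1e-10

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent oracle: scipy's Wahba solver on the centered clouds."""
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            w = rng.uniform(0.5, 2.0, size=12)
            t = kabsch(a, b, weights=w)
            ca = (w[:, None] * a).sum(0) / w.sum()
            cb = (w[:, None] * b).sum(0) / w.sum()
            rot, _ = Rotation.align_vectors(b - cb, a - ca, weights=w)
            assert np.allclose(t.rotation, rot.as_matrix(), atol=1e-8)

    def test_mirrored_planar_cloud_yields_proper_rotation(self, rng):
        """A mirrored near-planar cloud tempts the SVD into a reflection;
        the determinant correction must keep det = +1 and still reach the
        best proper rotation (grid oracle over 3000 random rotations)."""
        flat = rng.normal(size=(30, 3)) * np.array([1.0, 1.0, 1e-4])
        mirrored = flat * np.array([1.0, 1.0, -1.0])
        t = kabsch(mirrored, flat)
        assert math.isclose(np.linalg.det(t.rotation), 1.0, abs_tol=1e-10)
        ours = rmsd(t.apply(mirrored), flat)
        samples = Rotation.random(3000, random_state=7)
        cm, cf = mirrored.mean(0), flat.mean(0)
        best = min(rmsd((mirrored - cm) @ R.as_matrix().T + cf, flat)
                   for R in samples)
        assert ours <= best + 1e-12

    def test_optimality_against_random_rotations(self, rng):
        a = rng.normal(size=(40, 3))
        b = rng.normal(size=(40, 3))
        t = kabsch(a, b)
        ours = rmsd(t.apply(a), b)
        ca, cb = a.mean(0), b.mean(0)
        for R in Rotation.random(1000, random_state=11):
            cand = rmsd((a - ca) @ R.as_matrix().T + cb, b)
            assert ours <= cand + 1e-12

    def test_too_few_atoms_rejected(self):
        with pytest.raises(MolkitError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rigid_invariance_of_rmsd_and_gyration(self, rng):
        coords = rng.normal(size=(50, 3))
        other = rng.normal(size=(50, 3))
        R = Rotation.random(random_state=3).as_matrix()
        v = np.array([0.3, -1.0, 2.0])
        assert math.isclose(rmsd(coords @ R.T + v, other @ R.T + v),
                            rmsd(coords, other), abs_tol=1e-9)
        assert math.isclose(radius_of_gyration(coords @ R.T + v, masses=np.ones(50)),
                            radius_of_gyration(coords, masses=np.ones(50)),
                            abs_tol=1e-9)


class TestGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), masses=[1.0]) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[0, 0, 0], [1.0, 0, 0]])
        assert math.isclose(radius_of_gyration(coords, masses=[1, 1]), 0.5)

    def test_direct_formula_oracle(self, rng):
        coords = rng.normal(size=(100, 3))
        m = rng.uniform(1, 16, size=100)
        c = (m[:, None] * coords).sum(0) / m.sum()
        expect = math.sqrt((m * ((coords - c) ** 2).sum(1)).sum() / m.sum())
        assert math.isclose(radius_of_gyration(coords, masses=m), expect,
                            rel_tol=1e-12)


def two_sphere_sasa(r1, r2, d, probe):
    """Closed-form accessible area of two overlapping spheres."""
    R1, R2 = r1 + probe, r2 + probe
    a1, a2 = 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d >= R1 + R2:
        return a1 + a2
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    return (a1 - 2 * math.pi * R1 * h1) + (a2 - 2 * math.pi * R2 * h2)


class TestSasa:
    def test_isolated_sphere_analytic(self):
        areas, total = sasa(np.zeros((1, 3)), probe_radius=0.14, radii=[0.15])
        expect = 4 * math.pi * 0.29 ** 2
        assert abs(total - expect) / expect < 0.01

    def test_distant_spheres_additive(self):
        coords = np.array([[0, 0, 0], [5.0, 0, 0]])
        _, total = sasa(coords, probe_radius=0.14, radii=[0.15, 0.18])
        expect = 4 * math.pi * (0.29 ** 2 + 0.32 ** 2)
        assert abs(total - expect) / expect < 0.01

    def test_two_sphere_overlap_matches_cap_formula(self):
        r1, r2, probe = 0.17, 0.15, 0.14
        for d in np.linspace(0.05, 0.6, 20):
            coords = np.array([[0, 0, 0], [d, 0, 0]])
            _, total = sasa(coords, probe_radius=probe, radii=[r1, r2],
                            n_points=960)
            expect = two_sphere_sasa(r1, r2, d, probe)
            assert abs(total - expect) / expect < 0.02, d

    def test_monotone_decrease_on_approach(self):
        prev = math.inf
        for d in np.linspace(0.7, 0.05, 20):
            coords = np.array([[0, 0, 0], [d, 0, 0]])
            _, total = sasa(coords, probe_radius=0.14, radii=[0.16, 0.16])
            assert total <= prev + 1e-9
            prev = total

    def test_unknown_radius_is_an_error(self, system_factory):
        from molkit import Atom, State, Topology, AccessKind, make_system
        top = Topology([Atom(name="XX", element="Xx")])
        sys_ = make_system(top, State(np.zeros((1, 3))), AccessKind.MutableSerial)
        with pytest.raises(MolkitError, match="radius"):
            sasa(sys_.select_all())

    def test_selection_interface(self, system_factory):
        sys_ = system_factory()
        areas, total = sasa(sys_.select_all(), n_points=240)
        assert len(areas) == sys_.n_atoms
        assert total > 0 and np.all(areas >= 0)
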