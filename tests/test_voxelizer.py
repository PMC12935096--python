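"""Voxel-grid rendering: channels, density, rotations, brute-force oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fragforge.elements import vdw_radius
from fragforge.fixtures import make_fixture
from fragforge.mol import InputError, Molecule
from fragforge.voxelizer import (
    DENSITY_CUTOFF_FACTOR,
    GRID_AXIS,
    GRID_POINTS,
    GRID_SPACING,
    IDENTITY_ROTATION,
    N_CHANNELS,
    random_rotation,
    smooth_density,
    voxelize,
)


def _cloud(elements, coords):
    return Molecule.from_atom_cloud(elements, np.asarray(coords, dtype=float))


def _single_atom_setup(receptor_element="C", offset=(0.0, 0.0, 0.0)):
    """One receptor atom at `offset` from a one-atom ligand at the origin."""
    receptor = _cloud([receptor_element], [offset])
    trimmed = _cloud(["C"], [(0.0, 0.0, 0.0)])
    return receptor, trimmed


class TestGridContract:
    def test_shape_and_nonnegativity(self, ethylbenzene_entry):
        from fragforge.fragmenter import fragment_complex

        x = fragment_complex(ethylbenzene_entry)[0]
        grid = voxelize(ethylbenzene_entry.receptor, x.trimmed_ligand, x.branch_atom)
        assert grid.values.shape == (N_CHANNELS, GRID_POINTS, GRID_POINTS, GRID_POINTS)
        assert np.all(grid.values >= 0) and np.all(np.isfinite(grid.values))

    def test_central_density_of_atom_at_center(self):
        """An atom sitting exactly on the branching atom peaks at the eight
        central grid points, at exp(-(d/r)^2) for the half-spacing diagonal."""
        receptor, trimmed = _single_atom_setup()
        grid = voxelize(receptor, trimmed, 0).values
        d_central = np.sqrt(3) * GRID_SPACING / 2
        expect = np.exp(-((d_central / vdw_radius("C")) ** 2))
        assert grid[0].max() == pytest.approx(expect, abs=1e-6)
        assert (grid[0] == grid[0].max()).sum() == 8

    def test_atom_beyond_cutoff_contributes_nothing(self):
        r = vdw_radius("C")
        far = GRID_POINTS * GRID_SPACING  # outside every grid point's cutoff
        receptor, trimmed = _single_atom_setup(offset=(far, 0, 0))
        grid = voxelize(receptor, trimmed, 0).values
        assert grid[0].sum() == 0.0

    def test_truncation_radius_respected(self):
        receptor, trimmed = _single_atom_setup()
        grid = voxelize(receptor, trimmed, 0).values
        r = vdw_radius("C")
        pts = np.stack(np.meshgrid(GRID_AXIS, GRID_AXIS, GRID_AXIS, indexing="ij"), -1)
        dist = np.linalg.norm(pts, axis=-1)
        assert np.all(grid[0][dist > DENSITY_CUTOFF_FACTOR * r] == 0.0)
        assert np.all(grid[0][dist <= DENSITY_CUTOFF_FACTOR * r] > 0.0)

    def test_iron_lands_in_receptor_other_channel(self):
        receptor, trimmed = _single_atom_setup("Fe", offset=(1.0, 0, 0))
        grid = voxelize(receptor, trimmed, 0).values
        assert grid[4].sum() > 0
        assert grid[[0, 1, 2, 3]].sum() == 0.0  # nothing in C/O/N/S receptor channels

    def test_ligand_sulfur_goes_to_ligand_other(self):
        receptor = _cloud(["C"], [(3.0, 0, 0)])
        trimmed = _cloud(["C", "S"], [(0, 0, 0), (1.5, 0, 0)])
        grid = voxelize(receptor, trimmed, 0).values
        assert grid[8].sum() > 0  # ligand-other holds the S
        assert grid[3].sum() == 0.0  # receptor-S channel untouched

    def test_additivity_of_coincident_atoms(self):
        receptor1 = _cloud(["C"], [(1.0, 0.5, 0)])
        receptor2 = _cloud(["C", "C"], [(1.0, 0.5, 0), (1.0, 0.5, 0)])
        trimmed = _cloud(["C"], [(0, 0, 0)])
        g1 = voxelize(receptor1, trimmed, 0).values
        g2 = voxelize(receptor2, trimmed, 0).values
        np.testing.assert_allclose(g2[0], 2 * g1[0], rtol=1e-6)  # receptor channel doubles
        np.testing.assert_array_equal(g2[5], g1[5])  # ligand channel untouched

    def test_branch_atom_out_of_range(self):
        receptor, trimmed = _single_atom_setup()
        with pytest.raises(InputError):
            voxelize(receptor, trimmed, 5)


class TestTransformProperties:
    def test_translation_equivariance(self, ethylbenzene_entry):
        from fragforge.fragmenter import fragment_complex

        x = fragment_complex(ethylbenzene_entry)[0]
        shift = np.array([7.3, -2.1, 4.4])
        rec2 = _cloud(
            ethylbenzene_entry.receptor.elements, ethylbenzene_entry.receptor.coords + shift
        )
        tri2 = _cloud(x.trimmed_ligand.elements, x.trimmed_ligand.coords + shift)
        g1 = voxelize(ethylbenzene_entry.receptor, x.trimmed_ligand, x.branch_atom).values
        g2 = voxelize(rec2, tri2, x.branch_atom).values
        np.testing.assert_allclose(g1, g2, atol=1e-6)

    def test_rotation_consistency(self, ethylbenzene_entry):
        """Voxelizing with rotation R equals voxelizing pre-rotated coordinates
        (about the branching atom) with the identity."""
        from fragforge.fragmenter import fragment_complex

        x = fragment_complex(ethylbenzene_entry)[0]
        quat = random_rotation(123)
        R = Rotation.from_quat(quat).as_matrix()
        center = x.trimmed_ligand.atoms[x.branch_atom].coords
        rec_rot = _cloud(
            ethylbenzene_entry.receptor.elements,
            (ethylbenzene_entry.receptor.coords - center) @ R.T + center,
        )
        tri_rot = _cloud(
            x.trimmed_ligand.elements, (x.trimmed_ligand.coords - center) @ R.T + center
        )
        g_rot_arg = voxelize(
            ethylbenzene_entry.receptor, x.trimmed_ligand, x.branch_atom, rotation=quat
        ).values
        g_pre = voxelize(rec_rot, tri_rot, x.branch_atom).values
        np.testing.assert_allclose(g_rot_arg, g_pre, atol=1e-5)

    def test_90_degree_rotation_permutes_grid_exactly(self):
        """A 90-degree rotation about z maps the grid onto itself, so values
        are exactly permuted (no interpolation error)."""
        receptor = _cloud(["C", "O"], [(1.5, 0.75, 0.0), (-0.75, 2.25, 0.75)])
        trimmed = _cloud(["C"], [(0.0, 0.0, 0.0)])
        quat = Rotation.from_euler("z", 90, degrees=True).as_quat()
        g0 = voxelize(receptor, trimmed, 0).values
        g90 = voxelize(receptor, trimmed, 0, rotation=quat).values
        # rotating coordinates by +90 about z: (x,y,z) -> (-y,x,z); on indices
        # this is a flip+transpose of the first two grid axes
        expected = np.rot90(g0, k=1, axes=(1, 2))
        np.testing.assert_allclose(g90, expected, atol=1e-6)

    def test_identity_rotation_is_noop(self, ethylbenzene_entry):
        from fragforge.fragmenter import fragment_complex

        x = fragment_complex(ethylbenzene_entry)[0]
        g0 = voxelize(ethylbenzene_entry.receptor, x.trimmed_ligand, x.branch_atom).values
        g1 = voxelize(
            ethylbenzene_entry.receptor, x.trimmed_ligand, x.branch_atom, IDENTITY_ROTATION
        ).values
        np.testing.assert_array_equal(g0, g1)


class TestRandomRotation:
    def test_deterministic_per_seed(self):
        assert np.array_equal(random_rotation(5), random_rotation(5))
        assert not np.array_equal(random_rotation(5), random_rotation(6))

    def test_unit_quaternion(self):
        for seed in range(20):
            assert np.linalg.norm(random_rotation(seed)) == pytest.approx(1.0, abs=1e-12)

    def test_uniformity_mean_rotation_matrix_near_zero(self):
        """For rotations uniform on SO(3), E[R] = 0; check each entry within
        3 standard errors over 10^4 samples."""
        n = 10_000
        mats = Rotation.from_quat([random_rotation(s) for s in range(n)]).as_matrix()
        mean = mats.mean(axis=0)
        # entries of a uniform rotation matrix have variance 1/3
        se = np.sqrt(1.0 / 3.0 / n)
        assert np.all(np.abs(mean) < 3 * se + 1e-12)


class TestBruteForceOracle:
    def test_matches_production_on_random_fixtures(self):
        """Triple-loop density computation agrees with the sub-box
        implementation to 1e-6 on 10 random fixtures."""
        from fragforge.fragmenter import fragment_complex
        from fragforge.voxelizer import prepare_example

        for seed in range(10):
            entry = make_fixture(seed + 100, 20, "CCO" if seed % 2 else "CCc1ccccc1")
            examples = fragment_complex(entry)
            if not examples:
                continue
            x = examples[0]
            got = voxelize(entry.receptor, x.trimmed_ligand, x.branch_atom).values
            prep = prepare_example(entry.receptor, x.trimmed_ligand, x.branch_atom)
            want = np.zeros_like(got, dtype=np.float64)
            for i in range(GRID_POINTS):
                for j in range(GRID_POINTS):
                    for k in range(GRID_POINTS):
                        p = np.array([GRID_AXIS[i], GRID_AXIS[j], GRID_AXIS[k]])
                        d = np.linalg.norm(prep.coords - p, axis=1)
                        for a in range(len(d)):
                            r = prep.radii[a]
                            if d[a] <= DENSITY_CUTOFF_FACTOR * r:
                                want[prep.channels[a], i, j, k] += np.exp(-((d[a] / r) ** 2))
            np.testing.assert_allclose(got, want.astype(np.float32), atol=1e-6)
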