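"""Superposition, ensemble RMSD, restraint classes, interfaces, sequences."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mydgf_nmr.ensemble import (
    RegionSet,
    RestraintClassCounts,
    classify_restraints,
    ensemble_rmsd,
    interface_residues,
    kabsch_superpose,
    sequence_props,
)
from mydgf_nmr.io_formats import AtomRecord, RestraintRecord, StructureEnsemble
from mydgf_nmr.synthetic import EnsembleScenario, make_base_coordinates, make_ensemble


def brute_force_min_rmsd(mobile, target, step_deg=10):
    """Oracle: minimum RMSD over a zyz Euler-angle rotation grid."""
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    grid = np.deg2rad(np.arange(0, 360, step_deg))
    half = np.deg2rad(np.arange(0, 180 + step_deg, step_deg))
    angles = np.array(np.meshgrid(grid, half, grid)).reshape(3, -1).T
    mats = Rotation.from_euler("zyz", angles).as_matrix()  # (n, 3, 3)
    rotated = np.einsum("nij,kj->nki", mats, p)  # (n, k, 3)
    rmsds = np.sqrt(np.mean(np.sum((rotated - q) ** 2, axis=2), axis=1))
    return float(rmsds.min())


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_exact_rigid_motion_recovered(self, rng):
        target = rng.normal(size=(25, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        mobile = target @ rot.T + np.array([1.0, -2.0, 0.5])
        res = kabsch_superpose(mobile, target)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.apply(mobile), target, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)

    def test_beats_rotation_grid_oracle(self, rng):
        """Kabsch RMSD <= the minimum over a 10-degree brute-force grid for
        20 random 5-point clouds."""
        for _ in range(20):
            mobile = rng.normal(size=(5, 3))
            target = rng.normal(size=(5, 3))
            assert (
                kabsch_superpose(mobile, target).rmsd
                <= brute_force_min_rmsd(mobile, target) + 1e-9
            )

    def test_agrees_with_scipy_align_vectors(self, rng):
        """Independent cross-check against scipy's Wahba solver."""
        mobile = rng.normal(size=(12, 3))
        target = mobile @ Rotation.random(random_state=8).as_matrix().T + 3.0
        target += rng.normal(scale=0.1, size=target.shape)
        ours = kabsch_superpose(mobile, target)
        rot, rssd = Rotation.align_vectors(
            target - target.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(ours.rotation, rot.as_matrix(), atol=1e-8)
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(mobile)), abs=1e-8)


class TestEnsembleRmsd:
    def _region(self, atoms):
        lo = min(a.residue_number for a in atoms)
        hi = max(a.residue_number for a in atoms)
        return RegionSet(ranges=((lo, hi),), atom_selection="heavy")

    def test_identical_models_zero(self):
        atoms, coords = make_base_coordinates(n_residues=10, seed=0)
        ens = StructureEnsemble(list(atoms), np.stack([coords] * 4))
        mean, sd, per_model = ensemble_rmsd(ens, self._region(atoms))
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)
        assert len(per_model) == 3

    def test_jittered_matches_monte_carlo_expectation(self):
        from mydgf_nmr.recovery import ensemble_rmsd_recovery

        out = ensemble_rmsd_recovery(n_models=20, n_atoms_target=500, jitter_sd=0.5, seed=4)
        assert out["rmsd_mean_A"] == pytest.approx(out["mc_expected_rmsd_A"], rel=0.05)

    def test_rigid_motion_invariance(self):
        """Rotating + translating the whole ensemble leaves the RMSD unchanged."""
        atoms, coords = make_base_coordinates(n_residues=20, seed=5)
        ens = make_ensemble(
            EnsembleScenario(atoms, coords, n_models=5, jitter_sd=0.3, seed=6)
        )
        region = self._region(atoms)
        mean0, _, _ = ensemble_rmsd(ens, region)
        rot = Rotation.random(random_state=11).as_matrix()
        moved = StructureEnsemble(ens.atoms, ens.coords @ rot.T + np.array([4.0, -7.0, 2.0]))
        mean1, _, _ = ensemble_rmsd(moved, region)
        assert mean1 == pytest.approx(mean0, abs=1e-9)

    def test_empty_region_rejected(self):
        atoms, coords = make_base_coordinates(n_residues=5, seed=0)
        ens = StructureEnsemble(list(atoms), np.stack([coords] * 2))
        with pytest.raises(ValueError, match="no atoms"):
            ensemble_rmsd(ens, RegionSet(ranges=((900, 901),)))

    def test_backbone_selection_subset_of_heavy(self):
        atoms, coords = make_base_coordinates(n_residues=8, atoms_per_residue=5, seed=2)
        ens = StructureEnsemble(list(atoms), np.stack([coords, coords + 0.2]))
        lo = min(a.residue_number for a in atoms)
        hi = max(a.residue_number for a in atoms)
        bb = RegionSet(ranges=((lo, hi),), atom_selection="backbone")
        assert bb.mask(ens).sum() == 8 * 3  # N, CA, C
        bb_o = RegionSet(ranges=((lo, hi),), atom_selection="backbone", include_carbonyl_o=True)
        assert bb_o.mask(ens).sum() == 8 * 4


class TestRestraintClasses:
    def test_same_residue_is_short(self):
        counts = classify_restraints([RestraintRecord(10, "HA", 10, "HB", 3.0)])
        assert (counts.short, counts.medium, counts.long) == (1, 0, 0)

    def test_boundary_separations(self):
        records = [
            RestraintRecord(1, "HA", 2, "HN", 3.0),   # |i-j| = 1 -> short
            RestraintRecord(1, "HA", 4, "HN", 3.0),   # 3 -> medium
            RestraintRecord(1, "HA", 6, "HN", 3.0),   # 5 -> medium
            RestraintRecord(1, "HA", 10, "HN", 3.0),  # 9 -> long
        ]
        counts = classify_restraints(records)
        assert (counts.short, counts.medium, counts.long) == (1, 2, 1)

    def test_partition_exact_and_permutation_invariant(self, rng):
        records = [
            RestraintRecord(int(i), "HA", int(j), "HN", 3.0)
            for i, j in rng.integers(1, 140, size=(300, 2))
        ]
        counts = classify_restraints(records)
        assert counts.total == 300
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert classify_restraints(shuffled) == counts


class TestInterface:
    def _single_atom(self, xyz, res=1):
        atoms = [AtomRecord("A", res, "ALA", "CA", element="C")]
        return StructureEnsemble(atoms, np.asarray(xyz, dtype=float).reshape(1, 1, 3))

    def test_pair_below_cutoff_included(self):
        a = self._single_atom([0, 0, 0])
        b = self._single_atom([4.9, 0, 0])
        assert interface_residues(a, b, cutoff=5.0) == {1}

    def test_pair_above_cutoff_excluded(self):
        a = self._single_atom([0, 0, 0])
        b = self._single_atom([5.1, 0, 0])
        assert interface_residues(a, b, cutoff=5.0) == set()

    def test_matches_brute_force_scan(self, rng):
        atoms_a, coords_a = make_base_coordinates(n_residues=25, seed=1, extent=12.0)
        atoms_b, coords_b = make_base_coordinates(n_residues=25, seed=2, extent=12.0)
        a = StructureEnsemble(list(atoms_a), coords_a[None])
        b = StructureEnsemble(list(atoms_b), coords_b[None] + 15.0)
        expected = set()
        for atom, xyz in zip(atoms_a, coords_a):
            d = np.linalg.norm((coords_b + 15.0) - xyz, axis=1)
            if (d <= 5.0).any():
                expected.add(atom.residue_number)
        assert interface_residues(a, b, cutoff=5.0) == expected

    def test_monotone_in_cutoff(self, rng):
        atoms_a, coords_a = make_base_coordinates(n_residues=15, seed=3)
        atoms_b, coords_b = make_base_coordinates(n_residues=15, seed=4)
        a = StructureEnsemble(list(atoms_a), coords_a[None])
        b = StructureEnsemble(list(atoms_b), coords_b[None] + 8.0)
        small = interface_residues(a, b, cutoff=4.0)
        large = interface_residues(a, b, cutoff=7.0)
        assert small <= large

    def test_hydrogens_excluded(self):
        atoms = [
            AtomRecord("A", 1, "ALA", "CA", element="C"),
            AtomRecord("A", 2, "ALA", "HA", element="H"),
        ]
        a = StructureEnsemble(atoms, np.array([[[0, 0, 0], [1, 0, 0]]], dtype=float))
        b = self._single_atom([1.5, 0, 0], res=9)
        # residue 2 only approaches through its hydrogen -> not an interface residue
        assert interface_residues(a, b, cutoff=2.0) == {1}


class TestSequenceProps:
    def test_single_glycine(self):
        props = sequence_props("G")
        assert props.average_mass_da == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert sequence_props("GG").average_mass_da == pytest.approx(132.12, abs=0.01)

    def test_mass_additive_minus_water(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        a = "".join(rng.choice(letters, size=12))
        b = "".join(rng.choice(letters, size=9))
        water = 18.015
        combined = sequence_props(a + b).average_mass_da
        assert combined == pytest.approx(
            sequence_props(a).average_mass_da + sequence_props(b).average_mass_da - water,
            abs=0.01,
        )

    def test_disulfide_reduces_mass_by_two_hydrogens(self):
        seq = "ACDCK"
        red = sequence_props(seq, n_disulfides=0)
        ox = sequence_props(seq, n_disulfides=1)
        assert red.average_mass_da - ox.average_mass_da == pytest.approx(2 * 1.00794)

    def test_extinction_rule(self):
        props = sequence_props("WWYC" + "CG", n_disulfides=1)
        assert props.extinction_280 == 2 * 5500 + 1490 + 125

    def test_beers_law_concentration(self):
        props = sequence_props("W")  # eps = 5500
        assert props.concentration(a280=0.55, pathlength_cm=1.0) == pytest.approx(1e-4)

    def test_unknown_residue_position_reported(self):
        with pytest.raises(ValueError, match="position 3"):
            sequence_props("GGXG")

    def test_too_many_disulfides_rejected(self):
        with pytest.raises(ValueError, match="cysteine"):
            sequence_props("ACG", n_disulfides=1)
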