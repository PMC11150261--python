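"""CoMSIA similarity fields, grid construction and descriptor assembly."""

import math

import numpy as np
import pytest

from chromqsar.dataset import AtomRecord, MoleculeRecord
from chromqsar.fields import (
    FieldKind,
    FieldMatrix,
    FieldParams,
    GridSpec,
    assemble_descriptor_matrix,
    build_grid,
    compute_field_matrices,
    read_dx,
    similarity_field,
    write_dx,
)


def point_molecule(position, mol_id="pt", **props):
    defaults = dict(partial_charge=0.0, vdw_radius=1.70, hydrophobicity=0.0)
    defaults.update(props)
    atom = AtomRecord(element="C", position=np.asarray(position, float), **defaults)
    return MoleculeRecord(id=mol_id, atoms=[atom], molecular_weight=12.011)


class TestBuildGrid:
    def test_single_atom_box_arithmetic(self):
        grid = build_grid([point_molecule([0, 0, 0])], FieldParams(grid_margin=4.0, grid_spacing=2.0))
        assert np.allclose(grid.origin, [-4, -4, -4])
        assert grid.counts == (5, 5, 5)

    def test_all_atoms_contained(self, benchmark):
        grid = build_grid(benchmark["molecules"])
        for mol in benchmark["molecules"]:
            assert grid.contains(mol.coords).all()

    def test_disjoint_molecules_expanded_union_box(self):
        m1 = point_molecule([0, 0, 0], "a")
        m2 = point_molecule([10, 0, 0], "b")
        grid = build_grid([m1, m2], FieldParams(grid_margin=4.0, grid_spacing=2.0))
        assert np.allclose(grid.origin, [-4, -4, -4])
        hi = grid.origin + grid.spacing * (np.array(grid.counts) - 1)
        assert hi[0] >= 14.0 and grid.counts == (10, 5, 5)

    def test_empty_molecule_list_rejected(self):
        with pytest.raises(ValueError):
            build_grid([])


class TestSimilarityField:
    def test_zero_charges_give_zero_electrostatic_field(self):
        mol = point_molecule([1.0, 2.0, 3.0], partial_charge=0.0)
        grid = build_grid([mol])
        assert np.all(similarity_field(mol, grid, FieldKind.ELECTROSTATIC) == 0.0)

    def test_single_atom_hand_computed_gaussian(self):
        """Steric index at 2 Å from a carbon: −1.70³·exp(−0.3·4) ≈ −1.4798."""
        mol = point_molecule([0.0, 0.0, 0.0])
        grid = GridSpec(origin=np.array([2.0, 0.0, 0.0]), spacing=2.0, counts=(1, 1, 1))
        value = similarity_field(mol, grid, FieldKind.STERIC)[0]
        expected = -(1.70**3) * math.exp(-0.3 * 4.0)
        assert value == pytest.approx(expected, abs=1e-10)
        assert value == pytest.approx(-1.4798, abs=1e-3)

    def test_grid_point_on_atom_gives_minus_weight(self):
        mol = point_molecule([0.0, 0.0, 0.0], hydrophobicity=0.7)
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, counts=(1, 1, 1))
        assert similarity_field(mol, grid, FieldKind.HYDROPHOBIC)[0] == pytest.approx(-0.7, abs=1e-12)

    def test_sign_convention_for_positive_weights(self):
        """Positive atomic weights and probes give non-positive indices."""
        mol = point_molecule([0.5, 0.5, 0.5], hydrophobicity=0.3, is_donor=True, is_acceptor=True)
        grid = build_grid([mol])
        for kind in (FieldKind.STERIC, FieldKind.HYDROPHOBIC, FieldKind.DONOR, FieldKind.ACCEPTOR):
            assert np.all(similarity_field(mol, grid, kind) <= 0.0)

    def test_translation_invariance(self):
        mol = point_molecule([0.3, -0.2, 0.9], partial_charge=0.25)
        grid = build_grid([mol])
        shift = np.array([3.7, -1.2, 0.4])
        shifted_mol = mol.with_coords(mol.coords + shift)
        shifted_grid = GridSpec(origin=grid.origin + shift, spacing=grid.spacing, counts=grid.counts)
        for kind in FieldKind:
            a = similarity_field(mol, grid, kind)
            b = similarity_field(shifted_mol, shifted_grid, kind)
            assert np.allclose(a, b, atol=1e-10)

    def test_superposition_of_two_atoms(self):
        a1 = point_molecule([0.0, 0.0, 0.0], "a", partial_charge=0.2)
        a2 = point_molecule([1.5, 0.5, -0.5], "b", partial_charge=-0.2)
        both = MoleculeRecord(id="ab", atoms=[a1.atoms[0], a2.atoms[0]], molecular_weight=24.0)
        grid = build_grid([both])
        for kind in (FieldKind.STERIC, FieldKind.ELECTROSTATIC):
            combined = similarity_field(both, grid, kind)
            summed = similarity_field(a1, grid, kind) + similarity_field(a2, grid, kind)
            assert np.allclose(combined, summed, atol=1e-12)

    def test_monotone_decay_and_far_field(self):
        """|field| decays with distance; at 10 Å it is < 1e−12 of the 0 Å value."""
        mol = point_molecule([0.0, 0.0, 0.0])
        distances = np.arange(0.0, 10.5, 0.5)
        grid = GridSpec(origin=np.zeros(3), spacing=0.5, counts=(21, 1, 1))
        values = np.abs(similarity_field(mol, grid, FieldKind.STERIC))
        assert np.all(np.diff(values) < 0)
        assert values[-1] < 1e-12 * values[0]

    def test_clamp_limits_magnitude(self):
        mol = point_molecule([0.0, 0.0, 0.0], vdw_radius=4.0)  # weight 64
        grid = GridSpec(origin=np.zeros(3), spacing=1.0, counts=(1, 1, 1))
        value = similarity_field(mol, grid, FieldKind.STERIC, FieldParams(clamp_magnitude=30.0))[0]
        assert value == -30.0

    def test_unknown_field_kind_rejected(self):
        mol = point_molecule([0, 0, 0])
        grid = build_grid([mol])
        with pytest.raises(ValueError):
            similarity_field(mol, grid, "bogus")


class TestAssembleDescriptorMatrix:
    def test_constant_columns_dropped_and_blocks_equalized(self):
        rng = np.random.default_rng(0)
        steric = np.hstack([rng.normal(size=(10, 4)), np.full((10, 2), 7.0)])
        electro = rng.normal(scale=40.0, size=(10, 3))
        dm = assemble_descriptor_matrix(
            [FieldMatrix(FieldKind.STERIC, steric), FieldMatrix(FieldKind.ELECTROSTATIC, electro)],
            filter_sd=0.01,
        )
        assert dm.X.shape == (10, 7)  # two constant columns dropped
        kinds = [k for k, _ in dm.column_meta]
        assert kinds.count(FieldKind.STERIC) == 4
        # equal total variance per block
        for idx in dm.block_slices.values():
            assert dm.X[:, idx].var(axis=0).sum() == pytest.approx(1.0, abs=1e-9)
        # columns centered
        assert np.allclose(dm.X.mean(axis=0), 0.0, atol=1e-12)

    def test_hand_assembled_fixture(self):
        """3 molecules × 2 grid points against a hand-built matrix."""
        steric = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])  # col 1 constant
        dm = assemble_descriptor_matrix([FieldMatrix(FieldKind.STERIC, steric)], filter_sd=0.01)
        centered = np.array([-1.0, 0.0, 1.0])
        scale = math.sqrt(centered.var())
        assert dm.column_meta == [(FieldKind.STERIC, 0)]
        assert np.allclose(dm.X[:, 0], centered / scale)
        assert dm.column_means[0] == pytest.approx(2.0)

    def test_all_columns_filtered_is_error(self):
        constant = np.full((5, 3), 2.5)
        with pytest.raises(ValueError, match="filtered"):
            assemble_descriptor_matrix([FieldMatrix(FieldKind.STERIC, constant)])

    def test_transform_matches_training_preprocessing(self, benchmark_training):
        """Re-transforming the training field values reproduces X."""
        dm = benchmark_training["dm"]
        mols = benchmark_training["molecules"]
        fields = compute_field_matrices(mols, dm.grid)
        assert np.allclose(dm.transform(fields), dm.X, atol=1e-12)


class TestGridExport:
    def test_dx_round_trip_preserves_values_and_geometry(self, tmp_path):
        mol = point_molecule([0.1, 0.2, 0.3], partial_charge=0.4)
        grid = build_grid([mol])
        values = similarity_field(mol, grid, FieldKind.ELECTROSTATIC)
        path = tmp_path / "field.dx"
        write_dx(values, grid, path)
        back, spec = read_dx(path)
        assert spec.counts == grid.counts
        assert np.allclose(spec.origin, grid.origin, atol=1e-9)
        assert spec.spacing == pytest.approx(grid.spacing)
        assert np.allclose(back, values, atol=1e-9)
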