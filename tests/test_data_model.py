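"""Dataset containers, readers, splits, transforms, and the QM9-like rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molkd.data_model import (
    Dataset,
    Molecule3D,
    PropertyTable,
    SplitSpec,
    embed_conformer,
    fit_target_transform,
    load_smiles_table,
    load_structures,
    partition_qm9_like,
    read_dataset,
    split_dataset,
    write_dataset,
    write_structures,
)


class TestMolecule3D:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Molecule3D(np.array([1, 6]), np.zeros((3, 3)), "x")

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            Molecule3D(np.array([1, 1]), np.zeros((2, 3)), "x")

    def test_non_finite_rejected(self):
        pos = np.array([[0.0, 0.0, 0.0], [np.inf, 0.0, 0.0]])
        with pytest.raises(ValueError):
            Molecule3D(np.array([1, 1]), pos, "x")


class TestStructureFiles:
    def test_sdf_round_trip_counts_and_property(self, toy_dataset, tmp_path):
        path = tmp_path / "toy.sdf"
        write_structures(toy_dataset, str(path))
        ds = load_structures(str(path))
        assert len(ds) == 3
        assert ds.properties.property_names == ["energy"]
        np.testing.assert_allclose(ds.properties.values[:, 0], [1, 2, 3])
        for orig, back in zip(toy_dataset.molecules, ds.molecules):
            np.testing.assert_array_equal(orig.atomic_numbers, back.atomic_numbers)
            np.testing.assert_allclose(orig.positions, back.positions, atol=1e-4)

    def test_xyz_round_trip_tight_tolerance(self, small_dataset, tmp_path):
        sub = Dataset(
            small_dataset.molecules[:10],
            PropertyTable(
                small_dataset.properties.property_names,
                small_dataset.properties.values[:10],
            ),
        )
        path = tmp_path / "sub.xyz"
        write_structures(sub, str(path))
        back = load_structures(str(path))
        for orig, rec in zip(sub.molecules, back.molecules):
            np.testing.assert_array_equal(orig.atomic_numbers, rec.atomic_numbers)
            np.testing.assert_allclose(orig.positions, rec.positions, atol=1e-6)

    def test_malformed_xyz_names_line(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\ncomment\nC 0.0 0.0 0.0\nH 1.0 bad 0.0\n")
        with pytest.raises(ValueError, match="line 4"):
            load_structures(str(path))

    def test_dataset_container_round_trip(self, small_dataset, tmp_path):
        sdf, csv = tmp_path / "d.sdf", tmp_path / "d.csv"
        write_dataset(small_dataset, str(sdf), str(csv))
        back = read_dataset(str(sdf), str(csv))
        assert len(back) == len(small_dataset)
        np.testing.assert_allclose(
            back.properties.values, small_dataset.properties.values, rtol=1e-9
        )
        np.testing.assert_array_equal(back.split_labels, small_dataset.split_labels)


class TestSmilesTable:
    def _write(self, tmp_path, rows, header="smiles,sol"):
        path = tmp_path / "table.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return str(path)

    def test_three_row_table(self, tmp_path):
        path = self._write(tmp_path, ["CCO,-0.77", "CC,1.2", "O,0.5"])
        ds = load_smiles_table(path, "smiles", ["sol"])
        assert len(ds) == 3
        assert ds.molecules[0].positions is None
        np.testing.assert_allclose(ds.properties.values[:, 0], [-0.77, 1.2, 0.5])

    def test_invalid_smiles_names_row(self, tmp_path):
        path = self._write(tmp_path, ["CCO,-0.77", "not_a_smiles,0.0"])
        with pytest.raises(ValueError, match=r"row\(s\) \[1\]"):
            load_smiles_table(path, "smiles", ["sol"])

    def test_duplicates_warn_and_keep(self, tmp_path):
        path = self._write(tmp_path, ["CCO,-0.77", "CCO,-0.70"])
        with pytest.warns(UserWarning, match="duplicate"):
            ds = load_smiles_table(path, "smiles", ["sol"])
        assert len(ds) == 2

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, ["CCO,-0.77"])
        with pytest.raises(ValueError, match="missing column"):
            load_smiles_table(path, "smiles", ["logS"])


class TestEmbedConformer:
    def test_ethane_geometry_bounds(self):
        mol = Molecule3D(np.array([6]), None, "ethane", smiles="CC")
        out = embed_conformer(mol, seed=0)
        assert out.n_atoms == 8
        d = out.pairwise_distances()
        iu = np.triu_indices(8, 1)
        assert d[iu].min() > 0.5
        assert d[iu].max() < 4.0

    def test_deterministic_given_seed(self):
        mol = Molecule3D(np.array([6]), None, "m", smiles="CCO")
        a = embed_conformer(mol, seed=7)
        b = embed_conformer(mol, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_single_atom_at_origin(self):
        mol = Molecule3D(np.array([2]), None, "he", smiles="[He]")
        out = embed_conformer(mol, seed=0)
        assert out.n_atoms == 1
        np.testing.assert_array_equal(out.positions, np.zeros((1, 3)))


class TestSplit:
    def test_split_sizes_1000(self, small_dataset):
        cfg_sizes = {"train": 700, "val": 200, "test": 100}
        from molkd.synthetic import SyntheticConfig, generate_dataset

        ds = generate_dataset(
            SyntheticConfig(n_molecules=1000, atoms_per_molecule=(3, 5), seed=5)
        )
        ds = split_dataset(ds, SplitSpec())
        for name, size in cfg_sizes.items():
            assert len(ds.indices(name)) == size

    def test_split_sizes_9(self, toy_dataset):
        mols = toy_dataset.molecules * 3
        table = PropertyTable(
            ["energy"], np.arange(9, dtype=float).reshape(9, 1)
        )
        mols = [
            Molecule3D(m.atomic_numbers, m.positions, f"{m.source_id}_{i}")
            for i, m in enumerate(mols)
        ]
        ds = split_dataset(Dataset(mols, table), SplitSpec())
        assert len(ds.indices("train")) == 6
        assert len(ds.indices("val")) == 2
        assert len(ds.indices("test")) == 1

    def test_split_deterministic(self, small_dataset):
        a = split_dataset(small_dataset, SplitSpec(seed=3))
        b = split_dataset(small_dataset, SplitSpec(seed=3))
        np.testing.assert_array_equal(a.split_labels, b.split_labels)

    def test_split_is_partition(self, small_dataset):
        n = len(small_dataset)
        idx = np.concatenate(
            [small_dataset.indices(s) for s in ("train", "val", "test")]
        )
        assert sorted(idx.tolist()) == list(range(n))

    def test_empty_subset_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="larger dataset"):
            split_dataset(toy_dataset, SplitSpec())

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))

    @given(st.integers(min_value=10, max_value=400))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_split_proportions_within_one_over_n(self, n):
        mols = [
            Molecule3D(np.array([6]), np.zeros((1, 3)), f"m{i}") for i in range(n)
        ]
        ds = split_dataset(
            Dataset(mols, PropertyTable(["p"], np.zeros((n, 1)))), SplitSpec()
        )
        assert abs(len(ds.indices("val")) / n - 0.2) <= 1 / n
        assert abs(len(ds.indices("test")) / n - 0.1) <= 1 / n


class TestTargetTransform:
    def test_train_column_standardized(self, small_dataset):
        tr = fit_target_transform(small_dataset)
        idx = small_dataset.indices("train")
        z = tr.apply(small_dataset.properties.values[idx])
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_round_trip_identity(self, small_dataset):
        tr = fit_target_transform(small_dataset)
        y = small_dataset.properties.values
        np.testing.assert_allclose(tr.invert(tr.apply(y)), y, atol=1e-10)

    def test_constant_column_rejected(self, small_dataset):
        values = small_dataset.properties.values.copy()
        values[:, 0] = 5.0
        ds = Dataset(
            small_dataset.molecules,
            PropertyTable(small_dataset.properties.property_names, values),
            split_labels=small_dataset.split_labels,
        )
        with pytest.raises(ValueError, match="teacher_1"):
            fit_target_transform(ds)


class TestQm9LikePartition:
    def _dataset(self, mol_specs):
        mols = []
        for i, z in enumerate(mol_specs):
            z = np.asarray(z)
            pos = np.arange(len(z) * 3, dtype=float).reshape(-1, 3) * 1.5
            mols.append(Molecule3D(z, pos, f"m{i}"))
        return Dataset(mols, PropertyTable(["p"], np.zeros((len(mols), 1))))

    def test_element_and_size_rules(self):
        chlorobenzene = [6] * 6 + [1] * 5 + [17]
        benzene = [6] * 6 + [1] * 6
        big_cho = [6] * 10 + [8] * 2 + [1] * 4  # 12 heavy atoms
        ds = self._dataset([chlorobenzene, benzene, big_cho])
        like, unlike = partition_qm9_like(ds)
        assert like.tolist() == [1]
        assert unlike.tolist() == [0, 2]

    def test_partition_disjoint_exhaustive(self, small_dataset):
        like, unlike = partition_qm9_like(small_dataset)
        combined = sorted(np.concatenate([like, unlike]).tolist())
        assert combined == list(range(len(small_dataset)))
        assert set(like.tolist()).isdisjoint(unlike.tolist())
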