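"""Encoder contract: shapes, invariances, families, counting, checkpoints."""

import numpy as np
import pytest

from molkd.data_model import Molecule3D
from molkd.encoders import (
    EmbeddingMatrix,
    EncoderConfig,
    build_encoder,
    count_parameters,
    encode,
    load_encoder,
    make_student_family,
    predict,
    save_encoder,
)
from molkd.synthetic import QM9_PALETTE, generate_geometry
from tests.conftest import rigid_transform

CFG = EncoderConfig(
    hidden_dim=16, num_filters=8, num_interactions=2, num_rbf=8,
    output_properties=("p1", "p2"), seed=5,
)


@pytest.fixture(scope="module")
def molecules():
    return [generate_geometry(n, QM9_PALETTE, seed=n) for n in (4, 7, 10, 12)]


@pytest.fixture(scope="module")
def encoder():
    return build_encoder(CFG)


class TestEncode:
    def test_shape_and_finiteness(self, encoder, molecules):
        emb = encode(encoder, molecules)
        assert emb.values.shape == (4, CFG.hidden_dim)
        assert np.all(np.isfinite(emb.values))

    def test_permutation_invariance(self, encoder, molecules):
        mol = molecules[2]
        perm = np.random.default_rng(3).permutation(mol.n_atoms)
        permuted = Molecule3D(mol.atomic_numbers[perm], mol.positions[perm], "p")
        a = encode(encoder, [mol]).values
        b = encode(encoder, [permuted]).values
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_rigid_motion_invariance(self, encoder, molecules):
        mol = molecules[3]
        moved = Molecule3D(
            mol.atomic_numbers, rigid_transform(mol.positions, 9), "mv"
        )
        np.testing.assert_allclose(
            encode(encoder, [mol]).values, encode(encoder, [moved]).values,
            atol=1e-6,
        )

    def test_batching_independence(self, encoder, molecules):
        batched = encode(encoder, molecules).values
        single = np.vstack([encode(encoder, [m]).values for m in molecules])
        np.testing.assert_allclose(batched, single, atol=1e-6)

    def test_beyond_cutoff_atom_is_ignored(self, encoder):
        near = generate_geometry(5, QM9_PALETTE, seed=2)
        far_a = np.vstack([near.positions, [[50.0, 0.0, 0.0]]])
        far_b = np.vstack([near.positions, [[80.0, 0.0, 0.0]]])
        z = np.append(near.atomic_numbers, 6)
        ea = encode(encoder, [Molecule3D(z, far_a, "a")]).values
        eb = encode(encoder, [Molecule3D(z, far_b, "b")]).values
        np.testing.assert_allclose(ea, eb, atol=1e-6)

    def test_deterministic(self, encoder, molecules):
        a = encode(encoder, molecules).values
        b = encode(encoder, molecules).values
        np.testing.assert_array_equal(a, b)

    def test_element_above_z_max_rejected(self, encoder):
        mol = Molecule3D(np.array([120]), np.zeros((1, 3)), "exotic")
        with pytest.raises(ValueError, match="exceeds"):
            encode(encoder, [mol])

    def test_empty_batch_gives_empty_matrix(self, encoder):
        emb = encode(encoder, [])
        assert emb.values.shape == (0, CFG.hidden_dim)


class TestPredict:
    def test_zero_embedding_returns_bias(self, encoder):
        emb = EmbeddingMatrix(np.zeros((1, CFG.hidden_dim)), ["z"])
        np.testing.assert_allclose(
            predict(encoder, emb)[0], encoder.params["head_b"].data
        )

    def test_affine_linearity(self, encoder):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, CFG.hidden_dim))
        b = rng.normal(size=(3, CFG.hidden_dim))
        bias = encoder.params["head_b"].data
        lhs = predict(encoder, EmbeddingMatrix(a + b, list("xyz")))
        rhs = (
            predict(encoder, EmbeddingMatrix(a, list("xyz")))
            + predict(encoder, EmbeddingMatrix(b, list("xyz")))
            - bias
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_output_shape(self, encoder, molecules):
        emb = encode(encoder, molecules)
        assert predict(encoder, emb).shape == (4, 2)

    def test_width_mismatch_rejected(self, encoder):
        emb = EmbeddingMatrix(np.zeros((2, CFG.hidden_dim + 1)), ["a", "b"])
        with pytest.raises(ValueError, match="width"):
            predict(encoder, emb)


class TestStudentFamily:
    def test_filters_family(self):
        teacher = EncoderConfig(num_filters=128)
        fam = make_student_family(teacher, "filters", [8, 16, 32, 64])
        assert [c.num_filters for c in fam] == [8, 16, 32, 64]
        assert all(c.hidden_dim == teacher.hidden_dim for c in fam)

    def test_blocks_family(self):
        teacher = EncoderConfig(num_interactions=4)
        fam = make_student_family(teacher, "blocks", [1, 2, 3])
        assert [c.num_interactions for c in fam] == [1, 2, 3]

    def test_size_not_smaller_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            make_student_family(EncoderConfig(num_filters=128), "filters", [128])

    def test_embedding_width_constant_across_filters_family(self, molecules):
        teacher = EncoderConfig(hidden_dim=12, num_filters=16, num_rbf=8, seed=1)
        for cfg in make_student_family(teacher, "filters", [4, 8]):
            emb = encode(build_encoder(cfg), molecules)
            assert emb.values.shape[1] == 12


class TestParameterCount:
    def test_head_arithmetic(self):
        cfg = EncoderConfig(
            hidden_dim=4, num_filters=2, num_interactions=1, num_rbf=2,
            output_properties=tuple("abcde"), seed=0,
        )
        enc = build_encoder(cfg)
        head = enc.params["head_w"].data.size + enc.params["head_b"].data.size
        assert head == 4 * 5 + 5

    def test_monotone_in_filters(self):
        teacher = EncoderConfig(num_filters=64)
        counts = [
            count_parameters(build_encoder(c))
            for c in make_student_family(teacher, "filters", [8, 16, 32])
        ]
        assert counts == sorted(counts) and len(set(counts)) == 3

    def test_monotone_in_blocks(self):
        teacher = EncoderConfig(num_interactions=4)
        counts = [
            count_parameters(build_encoder(c))
            for c in make_student_family(teacher, "blocks", [1, 2, 3])
        ]
        assert counts == sorted(counts) and len(set(counts)) == 3

    def test_frozen_counts_zero(self):
        enc = build_encoder(CFG)
        assert count_parameters(enc) > 0
        enc.freeze()
        assert count_parameters(enc) == 0


class TestCheckpoint:
    def test_round_trip(self, encoder, molecules, tmp_path):
        path = tmp_path / "enc.ckpt"
        save_encoder(encoder, str(path))
        back = load_encoder(str(path))
        np.testing.assert_array_equal(
            encode(encoder, molecules).values, encode(back, molecules).values
        )

    def test_shape_mismatch_rejected(self, encoder, tmp_path):
        path = tmp_path / "enc.ckpt"
        save_encoder(encoder, str(path))
        other = build_encoder(CFG)
        bad = {k: v for k, v in other.state_arrays().items()}
        bad["head_w"] = bad["head_w"][:, :1]
        with pytest.raises(ValueError, match="mismatch"):
            other.load_state(bad)
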