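import os

# keep BLAS single-threaded before numpy loads: timings then match 1-core runs
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")

import numpy as np
import pytest

from molkd.data_model import Dataset, Molecule3D, PropertyTable, SplitSpec, split_dataset
from molkd.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """120 small synthetic molecules with split labels, for fast tests."""
    cfg = SyntheticConfig(n_molecules=120, atoms_per_molecule=(4, 8), seed=42)
    return split_dataset(generate_dataset(cfg), SplitSpec(seed=42))


@pytest.fixture()
def pair_molecule() -> Molecule3D:
    """Two identical atoms 1 Å apart — hand-checkable features."""
    return Molecule3D(
        np.array([6, 6]),
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        source_id="pair",
    )


@pytest.fixture()
def toy_dataset() -> Dataset:
    """Three tiny molecules with one property, no split."""
    mols = [
        Molecule3D(np.array([1]), np.zeros((1, 3)), source_id="a"),
        Molecule3D(
            np.array([6, 1]),
            np.array([[0.0, 0.0, 0.0], [1.1, 0.0, 0.0]]),
            source_id="b",
        ),
        Molecule3D(
            np.array([8, 1, 1]),
            np.array([[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]),
            source_id="c",
        ),
    ]
    table = PropertyTable(["energy"], np.array([[1.0], [2.0], [3.0]]))
    return Dataset(mols, table)


def rigid_transform(positions: np.ndarray, seed: int = 0) -> np.ndarray:
    """A random proper rotation plus translation."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return positions @ q.T + rng.normal(size=3)
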