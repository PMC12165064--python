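"""Molecules, property tables, splits, target normalization, and file readers.

A :class:`Molecule3D` is an atom-number sequence plus Cartesian coordinates in
Ångström — the unit of input to every encoder. A :class:`Dataset` pairs a list
of molecules with a :class:`PropertyTable` of named scalar targets and, once
split, carries per-molecule train/val/test labels. SMILES-only records (ESOL-
and FreeSolv-style tables) receive 3D coordinates from a seeded distance-
geometry conformer via :func:`embed_conformer`.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Molecule3D",
    "PropertyTable",
    "Dataset",
    "SplitSpec",
    "TargetTransform",
    "load_structures",
    "load_smiles_table",
    "embed_conformer",
    "split_dataset",
    "fit_target_transform",
    "partition_qm9_like",
    "write_structures",
    "write_dataset",
    "read_dataset",
]

QM9_ELEMENTS = frozenset({1, 6, 7, 8, 9})  # H, C, N, O, F
QM9_MAX_HEAVY_ATOMS = 9


@dataclass(frozen=True)
class Molecule3D:
    """One molecule: atomic numbers + 3D coordinates (Å).

    ``positions`` may be ``None`` for SMILES-only records that have not yet
    been through :func:`embed_conformer`.
    """

    atomic_numbers: np.ndarray
    positions: np.ndarray | None
    source_id: str
    smiles: str | None = None

    def __post_init__(self):
        z = np.asarray(self.atomic_numbers, dtype=np.int64)
        object.__setattr__(self, "atomic_numbers", z)
        if z.ndim != 1 or len(z) < 1 or np.any(z < 1):
            raise ValueError(f"molecule {self.source_id}: invalid atomic numbers")
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.float64)
            object.__setattr__(self, "positions", pos)
            if pos.shape != (len(z), 3):
                raise ValueError(
                    f"molecule {self.source_id}: positions shape {pos.shape} "
                    f"does not match {len(z)} atoms"
                )
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"molecule {self.source_id}: non-finite coordinates")
            if len(z) > 1 and self.min_distance() <= 0.0:
                raise ValueError(f"molecule {self.source_id}: coincident atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    @property
    def n_heavy_atoms(self) -> int:
        return int(np.sum(self.atomic_numbers > 1))

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def min_distance(self) -> float:
        d = self.pairwise_distances()
        iu = np.triu_indices(self.n_atoms, 1)
        return float(d[iu].min()) if iu[0].size else math.inf


@dataclass
class PropertyTable:
    """Named scalar targets, one row per molecule; NaN-free under the mask."""

    property_names: list[str]
    values: np.ndarray
    units: list[str] | None = None
    mask: np.ndarray | None = None  # True where a value is missing

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.units is None:
            self.units = ["a.u."] * len(self.property_names)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        if self.values.shape[1] != len(self.property_names):
            raise ValueError("values width does not match property_names")
        unmasked = self.values[~self.mask]
        if not np.all(np.isfinite(unmasked)):
            raise ValueError("non-finite unmasked property value")

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.property_names.index(name)]


@dataclass
class Dataset:
    molecules: list[Molecule3D]
    properties: PropertyTable
    provenance: str = "synthetic"
    split_labels: np.ndarray | None = None  # per-molecule: train/val/test

    def __post_init__(self):
        if self.properties.values.shape[0] != len(self.molecules):
            raise ValueError("property table row count does not match molecules")
        if self.split_labels is not None:
            labels = np.asarray(self.split_labels, dtype=object)
            if len(labels) != len(self.molecules):
                raise ValueError("split labels do not cover the dataset")
            if not set(labels) <= {"train", "val", "test"}:
                raise ValueError("split labels must be train/val/test")
            self.split_labels = labels

    def __len__(self) -> int:
        return len(self.molecules)

    def indices(self, split: str) -> np.ndarray:
        if self.split_labels is None:
            raise ValueError("dataset has not been split")
        return np.flatnonzero(self.split_labels == split)

    def subset_molecules(self, idx: np.ndarray) -> list[Molecule3D]:
        return [self.molecules[i] for i in idx]


@dataclass(frozen=True)
class SplitSpec:
    """Train/val/test fractions (default 70:20:10) plus shuffle seed."""

    fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be nonnegative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class TargetTransform:
    """Per-property z-score using train-split statistics only."""

    property_names: list[str]
    location: np.ndarray
    scale: np.ndarray
    fitted: bool = True

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if np.any(self.scale <= 0):
            bad = self.property_names[int(np.argmax(self.scale <= 0))]
            raise ValueError(f"non-positive scale for property {bad!r}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=np.float64) - self.location) / self.scale

    def invert(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=np.float64) * self.scale + self.location


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def load_structures(path: str, format: str | None = None) -> Dataset:
    """Read an SDF (V2000) or (extended) XYZ file into a Dataset.

    Extended XYZ: the comment line may carry whitespace-separated
    ``name=value`` scalar properties, collected into the property table.
    """
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "sdf":
        return _load_sdf(path)
    if format == "xyz":
        return _load_xyz(path)
    raise ValueError(f"unsupported structure format {format!r}")


def _load_sdf(path: str) -> Dataset:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
    molecules: list[Molecule3D] = []
    prop_rows: list[dict[str, float]] = []
    for rec, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unparsable SDF record at index {rec}")
        conf = mol.GetConformer()
        z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=np.int64)
        pos = np.array(conf.GetPositions(), dtype=np.float64)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        sid = name.strip() or f"record_{rec}"
        molecules.append(Molecule3D(z, pos, source_id=sid))
        row: dict[str, float] = {}
        for key in mol.GetPropNames():
            raw = mol.GetProp(key)
            try:
                row[key] = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric property column {key!r} in record {rec}"
                ) from exc
        prop_rows.append(row)
    names = sorted({k for row in prop_rows for k in row})
    values = np.full((len(molecules), len(names)), np.nan)
    for i, row in enumerate(prop_rows):
        for j, nm in enumerate(names):
            if nm in row:
                values[i, j] = row[nm]
    table = PropertyTable(names, values.reshape(len(molecules), len(names)))
    return Dataset(molecules, table, provenance="qm9-style")


def _load_xyz(path: str) -> Dataset:
    molecules: list[Molecule3D] = []
    prop_rows: list[dict[str, float]] = []
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, rec = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected atom count") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        row: dict[str, float] = {}
        for tok in comment.split():
            if "=" in tok:
                key, _, val = tok.partition("=")
                try:
                    row[key] = float(val)
                except ValueError as exc:
                    raise ValueError(f"non-numeric property column {key!r}") from exc
        z = np.empty(n, dtype=np.int64)
        pos = np.empty((n, 3), dtype=np.float64)
        for k in range(n):
            ln = i + 2 + k
            parts = lines[ln].split() if ln < len(lines) else []
            if len(parts) < 4:
                raise ValueError(f"line {ln + 1}: malformed coordinate line")
            sym = parts[0]
            z[k] = int(sym) if sym.isdigit() else pt.GetAtomicNumber(sym)
            try:
                pos[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ValueError(f"line {ln + 1}: malformed coordinate line") from exc
        molecules.append(Molecule3D(z, pos, source_id=f"record_{rec}"))
        prop_rows.append(row)
        rec += 1
        i += 2 + n
    names = sorted({k for row in prop_rows for k in row})
    values = np.full((len(molecules), max(len(names), 0)), np.nan)
    for r, row in enumerate(prop_rows):
        for j, nm in enumerate(names):
            if nm in row:
                values[r, j] = row[nm]
    table = PropertyTable(names, values.reshape(len(molecules), len(names)))
    return Dataset(molecules, table, provenance="qm9-style")


def write_structures(dataset: Dataset, path: str, format: str | None = None) -> None:
    """Write molecules (+ scalar properties) to SDF or extended XYZ.

    XYZ coordinates carry 10 decimals, so a write/read cycle round-trips to
    ~1e-9 Å; SDF V2000 fixes 4 decimals (1e-4 Å).
    """
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    if format == "xyz":
        _write_xyz(dataset, path)
    elif format == "sdf":
        _write_sdf(dataset, path)
    else:
        raise ValueError(f"unsupported structure format {format!r}")


def _write_xyz(dataset: Dataset, path: str) -> None:
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    table = dataset.properties
    with open(path, "w") as fh:
        for i, mol in enumerate(dataset.molecules):
            fh.write(f"{mol.n_atoms}\n")
            toks = [
                f"{nm}={table.values[i, j]:.12g}"
                for j, nm in enumerate(table.property_names)
                if not table.mask[i, j]
            ]
            fh.write(" ".join(toks) + "\n")
            for z, p in zip(mol.atomic_numbers, mol.positions):
                sym = pt.GetElementSymbol(int(z))
                fh.write(f"{sym} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def _write_sdf(dataset: Dataset, path: str) -> None:
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(path)
    try:
        table = dataset.properties
        for i, mol in enumerate(dataset.molecules):
            rw = Chem.RWMol()
            for z in mol.atomic_numbers:
                atom = Chem.Atom(int(z))
                atom.SetNoImplicit(True)
                rw.AddAtom(atom)
            conf = Chem.Conformer(mol.n_atoms)
            for k, p in enumerate(mol.positions):
                conf.SetAtomPosition(k, Point3D(*map(float, p)))
            m = rw.GetMol()
            m.AddConformer(conf)
            m.SetProp("_Name", mol.source_id)
            for j, nm in enumerate(table.property_names):
                if not table.mask[i, j]:
                    m.SetProp(nm, f"{table.values[i, j]:.12g}")
            writer.write(m)
    finally:
        writer.close()


def write_dataset(dataset: Dataset, structures_path: str, table_path: str) -> None:
    """Canonical container: one structures file + one CSV (source_id, split, props)."""
    write_structures(dataset, structures_path)
    df = pd.DataFrame(
        dataset.properties.values, columns=dataset.properties.property_names
    )
    df.insert(0, "source_id", [m.source_id for m in dataset.molecules])
    df.insert(
        1,
        "split",
        dataset.split_labels if dataset.split_labels is not None else "",
    )
    df.to_csv(table_path, index=False)


def read_dataset(structures_path: str, table_path: str) -> Dataset:
    ds = load_structures(structures_path)
    df = pd.read_csv(table_path)
    order = {sid: i for i, sid in enumerate(df["source_id"].astype(str))}
    idx = [order[m.source_id] for m in ds.molecules]
    prop_cols = [c for c in df.columns if c not in ("source_id", "split")]
    values = df.loc[idx, prop_cols].to_numpy(dtype=np.float64)
    labels = None
    if "split" in df.columns and df["split"].notna().all():
        lab = df.loc[idx, "split"].astype(str).to_numpy(dtype=object)
        if set(lab) <= {"train", "val", "test"}:
            labels = lab
    return Dataset(
        ds.molecules,
        PropertyTable(prop_cols, values),
        provenance=ds.provenance,
        split_labels=labels,
    )


def load_smiles_table(
    path: str,
    smiles_col: str,
    target_cols: list[str],
    units: dict[str, str] | None = None,
    provenance: str = "esol-style",
) -> Dataset:
    """Read a delimited SMILES+targets table (ESOL / FreeSolv layout).

    Molecules carry SMILES but no coordinates; run :func:`embed_conformer`
    before encoding. Invalid SMILES raise with the offending row numbers;
    duplicates warn but both rows are kept.
    """
    from rdkit import Chem

    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in [smiles_col, *target_cols] if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    bad_rows = []
    molecules = []
    seen: set[str] = set()
    dupes = []
    for i, smi in enumerate(df[smiles_col].astype(str)):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            bad_rows.append(i)
            continue
        z = np.array([a.GetAtomicNum() for a in Chem.AddHs(mol).GetAtoms()])
        if smi in seen:
            dupes.append(i)
        seen.add(smi)
        molecules.append(
            Molecule3D(z, None, source_id=f"row_{i}", smiles=smi)
        )
    if bad_rows:
        raise ValueError(f"invalid SMILES at row(s) {bad_rows}")
    if dupes:
        warnings.warn(f"duplicate SMILES at row(s) {dupes}; keeping all")
    values = df[target_cols].to_numpy(dtype=np.float64)
    unit_list = [units.get(c, "a.u.") if units else "a.u." for c in target_cols]
    return Dataset(
        molecules,
        PropertyTable(list(target_cols), values, units=unit_list),
        provenance=provenance,
    )


def embed_conformer(molecule: Molecule3D, seed: int, max_retries: int = 5) -> Molecule3D:
    """Attach one seeded low-energy distance-geometry 3D conformer.

    Hydrogens are made explicit before embedding; the geometry is relaxed
    with MMFF (falling back to UFF). Deterministic given ``seed``.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if molecule.smiles is None:
        raise ValueError(f"molecule {molecule.source_id} has no SMILES")
    mol = Chem.MolFromSmiles(molecule.smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES for molecule {molecule.source_id}")
    mol = Chem.AddHs(mol)
    if mol.GetNumAtoms() == 1:
        z = np.array([mol.GetAtomWithIdx(0).GetAtomicNum()])
        return replace(molecule, atomic_numbers=z, positions=np.zeros((1, 3)))
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        if AllChem.EmbedMolecule(mol, params) != 0:
            continue
        try:
            if AllChem.MMFFHasAllMoleculeParams(mol):
                AllChem.MMFFOptimizeMolecule(mol)
            else:
                AllChem.UFFOptimizeMolecule(mol)
        except Exception:
            pass
        z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()])
        pos = np.array(mol.GetConformer().GetPositions(), dtype=np.float64)
        out = replace(molecule, atomic_numbers=z, positions=pos)
        if out.min_distance() > 0.5:
            return out
    raise ValueError(
        f"conformer embedding failed for molecule {molecule.source_id}; "
        "flagged for exclusion"
    )


def split_dataset(dataset: Dataset, spec: SplitSpec = SplitSpec()) -> Dataset:
    """Assign train/val/test labels by seeded uniform shuffle.

    Sizes: ``n_val = round(f_val·n)``, ``n_test = round(f_test·n)`` (half away
    from zero), remainder to train — exact 70/20/10 whenever n is divisible
    by 10.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    f_train, f_val, f_test = spec.fractions
    n_val = _round_half_away(f_val * n)
    n_test = _round_half_away(f_test * n)
    n_train = n - n_val - n_test
    for name, size, frac in (
        ("train", n_train, f_train),
        ("val", n_val, f_val),
        ("test", n_test, f_test),
    ):
        if frac > 0 and size < 1:
            raise ValueError(
                f"{name} subset would be empty (n={n}); use a larger dataset"
            )
    perm = np.random.default_rng(spec.seed).permutation(n)
    labels = np.empty(n, dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train : n_train + n_val]] = "val"
    labels[perm[n_train + n_val :]] = "test"
    return Dataset(
        dataset.molecules, dataset.properties, dataset.provenance, labels
    )


def fit_target_transform(
    dataset: Dataset, properties: list[str] | None = None
) -> TargetTransform:
    """Fit a per-property z-score on the train split (sample sd, ddof=1)."""
    idx = dataset.indices("train")
    names = properties or dataset.properties.property_names
    cols = [dataset.properties.property_names.index(nm) for nm in names]
    y = dataset.properties.values[np.ix_(idx, cols)]
    loc = y.mean(axis=0)
    scale = y.std(axis=0, ddof=1)
    for j, nm in enumerate(names):
        if not scale[j] > 0:
            raise ValueError(f"zero train-split variance for property {nm!r}")
    return TargetTransform(list(names), loc, scale)


def partition_qm9_like(
    dataset: Dataset,
    element_whitelist: frozenset[int] | set[int] = QM9_ELEMENTS,
    max_heavy_atoms: int = QM9_MAX_HEAVY_ATOMS,
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (QM9-like, non-QM9-like) molecules.

    QM9-like ⇔ every element is whitelisted AND heavy-atom count ≤ cap.
    """
    like, unlike = [], []
    for i, mol in enumerate(dataset.molecules):
        ok = set(mol.atomic_numbers.tolist()) <= set(element_whitelist)
        if ok and mol.n_heavy_atoms <= max_heavy_atoms:
            like.append(i)
        else:
            unlike.append(i)
    return np.array(like, dtype=np.int64), np.array(unlike, dtype=np.int64)
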