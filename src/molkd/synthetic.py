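"""Synthetic 3D molecules with geometry-dependent scalar properties.

The generator emulates the statistical setting knowledge distillation relies
on: a set of "teacher" properties and a set of "transfer" properties that
share latent molecular signal. Every property is a linear form in five
permutation- and rigid-motion-invariant geometric descriptors, plus Gaussian
noise; the `shared_signal_rho` knob interpolates the transfer properties
between property-specific directions (rho=0) and the teacher's mean signal
direction (rho=1). These molecules are geometric fixtures, not chemicals: no
bonds, valence, or force-field realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import Dataset, Molecule3D, PropertyTable

__all__ = [
    "SyntheticConfig",
    "PropertyFamily",
    "generate_geometry",
    "latent_features",
    "make_property_family",
    "generate_molecules",
    "generate_dataset",
]

#: default element palette: QM9's elements with roughly organic abundances
QM9_PALETTE = {1: 0.50, 6: 0.30, 7: 0.09, 8: 0.08, 9: 0.03}
#: palette adding second-row elements for cross-domain / non-QM9-like studies
EXTENDED_PALETTE = {1: 0.42, 6: 0.28, 7: 0.08, 8: 0.08, 9: 0.03, 16: 0.06, 17: 0.05}

FEATURE_NAMES = (
    "gaussian_overlap",   # sum_{i<j} exp(-d_ij^2 / 2)
    "inverse_distance",   # sum_{i<j} 1 / d_ij
    "total_charge",       # sum_i Z_i
    "radius_of_gyration",
    "heavy_atom_count",
)
_PAIR_CUTOFF = 6.0  # Å; pairwise sums run over d_ij <= cutoff


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_molecules: int = 2000
    atoms_per_molecule: tuple[int, int] = (12, 12)  # inclusive range
    element_palette: dict[int, float] = field(
        default_factory=lambda: dict(QM9_PALETTE)
    )
    d_min: float = 0.9          # Å, minimum interatomic distance
    box_scale: float = 6.0      # Å, cap on distance from the first atom
    n_teacher_properties: int = 5
    n_transfer_properties: int = 10
    shared_signal_rho: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if not 0.0 <= self.shared_signal_rho <= 1.0:
            raise ValueError("shared_signal_rho must lie in [0, 1]")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be nonnegative")

    @property
    def property_names(self) -> list[str]:
        return [f"teacher_{k + 1}" for k in range(self.n_teacher_properties)] + [
            f"transfer_{m + 1}" for m in range(self.n_transfer_properties)
        ]


def generate_geometry(
    n_atoms: int,
    palette: dict[int, float],
    seed: int,
    d_min: float = 0.9,
    box_scale: float = 6.0,
    max_rejects: int = 500,
    source_id: str | None = None,
) -> Molecule3D:
    """Grow a random compact cluster by sequential shell placement.

    Each new atom is placed uniformly in the shell [d_min, 2·d_min] around a
    uniformly chosen existing atom and rejected until all pairwise distances
    are ≥ d_min and it stays within ``box_scale`` of the first atom.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    elements = np.array(sorted(palette), dtype=np.int64)
    weights = np.array([palette[z] for z in elements], dtype=np.float64)
    weights /= weights.sum()
    z = rng.choice(elements, size=n_atoms, p=weights)
    pos = np.zeros((n_atoms, 3))
    for k in range(1, n_atoms):
        for _ in range(max_rejects):
            anchor = pos[rng.integers(0, k)]
            vec = rng.normal(size=3)
            vec /= np.linalg.norm(vec)
            radius = rng.uniform(d_min, 2.0 * d_min)
            cand = anchor + radius * vec
            if np.linalg.norm(cand) > box_scale:
                continue
            if np.min(np.linalg.norm(pos[:k] - cand, axis=1)) >= d_min:
                pos[k] = cand
                break
        else:
            raise RuntimeError(
                "atom placement failed after bounded rejections; "
                "d_min/box_scale are mutually infeasible"
            )
    sid = source_id if source_id is not None else f"syn_{seed}"
    return Molecule3D(z, pos, source_id=sid)


def latent_features(molecule: Molecule3D) -> np.ndarray:
    """Five invariant descriptors driving all synthetic properties.

    Pairwise sums run over pairs with d_ij ≤ 6 Å; all five are invariant to
    atom reordering and to rigid motions of the coordinates.
    """
    pos = molecule.positions
    n = molecule.n_atoms
    if n > 1:
        iu = np.triu_indices(n, 1)
        d = np.sqrt(((pos[iu[0]] - pos[iu[1]]) ** 2).sum(-1))
        d = d[d <= _PAIR_CUTOFF]
        f1 = float(np.exp(-(d**2) / 2.0).sum())
        f2 = float((1.0 / d).sum())
    else:
        f1 = f2 = 0.0
    center = pos.mean(axis=0)
    rg = float(np.sqrt(((pos - center) ** 2).sum(-1).mean()))
    return np.array(
        [f1, f2, float(molecule.atomic_numbers.sum()), rg, molecule.n_heavy_atoms],
        dtype=np.float64,
    )


@dataclass(frozen=True)
class PropertyFamily:
    """Seeded linear property functions over the latent features.

    teacher_k  = a_k · (w_k · f̃) + ε
    transfer_m = b_m · (ρ · (w̄ · f̃) + (1 − ρ) · (v_m · f̃)) + ε

    with w_k, v_m random unit vectors, w̄ their (teacher) mean, f̃ the
    standardized feature vector, and ε drawn per (molecule index, property
    index) so adding properties or reordering coordinates never perturbs
    existing values. Features are standardized (population location/scale,
    fitted once per dataset via :meth:`with_feature_scaling`) so that all
    five descriptors — geometric and compositional — contribute comparable
    variance; on the raw scale the atomic-number sum would dominate every
    property and geometry would be irrelevant.
    """

    teacher_weights: np.ndarray      # (n_teacher, 5) unit rows
    transfer_weights: np.ndarray     # (n_transfer, 5) unit rows
    teacher_scales: np.ndarray       # a_k
    transfer_scales: np.ndarray      # b_m
    shared_signal_rho: float
    noise_sd: float
    noise_seed: int
    feature_location: np.ndarray = field(
        default_factory=lambda: np.zeros(len(FEATURE_NAMES))
    )
    feature_scale: np.ndarray = field(
        default_factory=lambda: np.ones(len(FEATURE_NAMES))
    )

    @property
    def mean_teacher_weight(self) -> np.ndarray:
        return self.teacher_weights.mean(axis=0)

    def with_feature_scaling(self, features: np.ndarray) -> "PropertyFamily":
        """Freeze population feature statistics into the family."""
        f = np.atleast_2d(features)
        scale = f.std(axis=0)
        if np.any(scale <= 0):
            raise ValueError("degenerate feature column; cannot standardize")
        return replace(self, feature_location=f.mean(axis=0), feature_scale=scale)

    def _standardize(self, features: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(features) - self.feature_location) / self.feature_scale

    def teacher_signal(self, features: np.ndarray) -> np.ndarray:
        """The shared signal w̄·f̃ distilled through the teacher."""
        return self._standardize(features) @ self.mean_teacher_weight

    def transfer_direction(self, m: int) -> np.ndarray:
        rho = self.shared_signal_rho
        return rho * self.mean_teacher_weight + (1 - rho) * self.transfer_weights[m]

    def evaluate(self, features: np.ndarray, noise: bool = True) -> np.ndarray:
        """Property matrix (n, n_teacher + n_transfer) for feature rows."""
        f = self._standardize(features)
        teacher = (f @ self.teacher_weights.T) * self.teacher_scales
        directions = np.stack(
            [self.transfer_direction(m) for m in range(len(self.transfer_weights))]
        )
        transfer = (f @ directions.T) * self.transfer_scales
        values = np.hstack([teacher, transfer])
        if noise and self.noise_sd > 0:
            values = values + self._noise(f.shape[0], values.shape[1])
        return values

    def _noise(self, n: int, p: int) -> np.ndarray:
        # counter-based: one child stream per property column, indexed draws
        cols = []
        for j in range(p):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.noise_seed, j])
            )
            cols.append(rng.normal(0.0, self.noise_sd, size=n))
        return np.column_stack(cols)

    def analytic_correlation(self, features: np.ndarray, m: int) -> float:
        """Closed-form corr(teacher signal, noise-free transfer_m) of the
        sampled linear forms, under the empirical covariance of a feature
        sample."""
        cov = np.cov(self._standardize(features).T)
        w = self.mean_teacher_weight
        u = self.transfer_direction(m)
        num = w @ cov @ u
        den = np.sqrt((w @ cov @ w) * (u @ cov @ u))
        return float(num / den)


def make_property_family(config: SyntheticConfig) -> PropertyFamily:
    """Draw and persist the seeded property coefficients for a config."""
    ss = np.random.SeedSequence([config.seed, 101])
    rng = np.random.default_rng(ss)

    def unit_rows(k: int) -> np.ndarray:
        w = rng.normal(size=(k, len(FEATURE_NAMES)))
        return w / np.linalg.norm(w, axis=1, keepdims=True)

    teacher_w = unit_rows(config.n_teacher_properties)
    transfer_w = unit_rows(config.n_transfer_properties)
    teacher_a = rng.uniform(0.5, 2.0, size=config.n_teacher_properties)
    transfer_b = rng.uniform(0.5, 2.0, size=config.n_transfer_properties)
    return PropertyFamily(
        teacher_weights=teacher_w,
        transfer_weights=transfer_w,
        teacher_scales=teacher_a,
        transfer_scales=transfer_b,
        shared_signal_rho=config.shared_signal_rho,
        noise_sd=float(config.noise_sd),
        noise_seed=config.seed + 7919,
    )


def generate_molecules(config: SyntheticConfig) -> list[Molecule3D]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = config.atoms_per_molecule
    seeds = rng.integers(0, 2**31 - 1, size=config.n_molecules)
    sizes = rng.integers(lo, hi + 1, size=config.n_molecules)
    return [
        generate_geometry(
            int(sizes[i]),
            config.element_palette,
            int(seeds[i]),
            d_min=config.d_min,
            box_scale=config.box_scale,
            source_id=f"syn_{config.seed}_{i}",
        )
        for i in range(config.n_molecules)
    ]


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> Dataset:
    """Full synthetic dataset: molecules + teacher/transfer property table.

    A pure function of the config (including its seed): identical configs
    produce byte-identical property tables.
    """
    molecules = generate_molecules(config)
    family = make_property_family(config)
    features = np.stack([latent_features(m) for m in molecules])
    family = family.with_feature_scaling(features)
    values = family.evaluate(features, noise=True)
    table = PropertyTable(config.property_names, values)
    return Dataset(molecules, table, provenance="synthetic")
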