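"""Teacher/student encoder contract and the reference continuous-filter encoder.

The contract is molecule → latent embedding → property predictions. The
reference backbone follows the continuous-filter convolution scheme: atom
states from a type-embedding table are refined by T interaction layers, each
generating per-neighbor filters from a Gaussian radial-basis expansion of the
interatomic distance, and are sum-pooled into a fixed-width molecular
embedding feeding per-property affine heads. Because only interatomic
distances enter, embeddings are exactly invariant to atom permutations and
rigid motions.

Student families shrink capacity along one axis — the number of filters F or
the number of interaction layers T — while keeping the embedding width H, so
teacher/student cosine similarity never needs a projection.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, replace

import numpy as np
from .autodiff import (
    ScatterPlan,
    Tensor,
    constant,
    gather_rows,
    parameter,
    segment_sum,
)
from .data_model import Molecule3D

__all__ = [
    "EncoderConfig",
    "Encoder",
    "EmbeddingMatrix",
    "BatchFeatures",
    "build_encoder",
    "encode",
    "predict",
    "make_student_family",
    "count_parameters",
    "featurize",
    "save_encoder",
    "load_encoder",
]


@dataclass(frozen=True)
class EncoderConfig:
    family: str = "reference-cfconv"
    hidden_dim: int = 64        # H: atom-state / embedding width
    num_filters: int = 64       # F: continuous-filter width
    num_interactions: int = 3   # T: interaction layers
    num_rbf: int = 32           # K: Gaussian radial basis functions
    cutoff: float = 6.0         # Å
    z_max: int = 100            # atom-type table size
    output_properties: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_dim", "num_filters", "num_interactions", "num_rbf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(
            self, "output_properties", tuple(self.output_properties)
        )


@dataclass
class EmbeddingMatrix:
    """n×d per-molecule latent embeddings, keyed by molecule ids."""

    values: np.ndarray
    molecule_ids: list[str]
    producer: str = "teacher"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.molecule_ids):
            raise ValueError("embedding rows do not match molecule ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding values")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows_for(self, ids: list[str]) -> np.ndarray:
        index = {mid: i for i, mid in enumerate(self.molecule_ids)}
        missing = [mid for mid in ids if mid not in index]
        if missing:
            raise KeyError(f"missing teacher embeddings for molecules {missing}")
        return self.values[[index[mid] for mid in ids]]


@dataclass
class BatchFeatures:
    """Precomputed constants for one batch of molecules.

    Geometry never needs gradients, so the radial expansion and the
    gather/scatter/pooling index plans are built once per batch and reused
    every epoch.
    """

    z: np.ndarray            # (n_atoms,) atomic numbers
    rbf: np.ndarray          # (n_edges, K)
    edge_src: np.ndarray     # (n_edges,) neighbor atom j per edge
    edge_plan: ScatterPlan   # edges → target atoms i (message aggregation)
    src_plan: ScatterPlan    # backward plan for the neighbor gather
    pool_plan: ScatterPlan   # atoms → molecules (sum pooling)
    molecule_ids: list[str]


def _rbf_expand(d: np.ndarray, num_rbf: int, cutoff: float) -> np.ndarray:
    centers = np.linspace(0.0, cutoff, num_rbf)
    gamma = 1.0 if num_rbf < 2 else centers[1] - centers[0]
    return np.exp(-((d[:, None] - centers[None, :]) ** 2) / (2.0 * gamma**2))


def featurize(
    molecules: list[Molecule3D], config: EncoderConfig
) -> BatchFeatures:
    """Build the constant per-batch operators for the reference encoder."""
    z_list, ei, ej, dists = [], [], [], []
    mol_of_atom = []
    offset = 0
    for mi, mol in enumerate(molecules):
        n = mol.n_atoms
        bad = mol.atomic_numbers[mol.atomic_numbers > config.z_max]
        if bad.size:
            raise ValueError(
                f"molecule {mol.source_id}: element Z={int(bad[0])} exceeds "
                f"z_max={config.z_max}"
            )
        z_list.append(mol.atomic_numbers)
        if n > 1:
            d = mol.pairwise_distances()
            src, dst = np.nonzero((d <= config.cutoff) & ~np.eye(n, dtype=bool))
            ei.append(src + offset)
            ej.append(dst + offset)
            dists.append(d[src, dst])
        mol_of_atom.append(np.full(n, mi))
        offset += n
    z = np.concatenate(z_list)
    n_atoms = offset
    if ei:
        ei = np.concatenate(ei)
        ej = np.concatenate(ej)
        d = np.concatenate(dists)
    else:
        ei = ej = np.empty(0, dtype=np.int64)
        d = np.empty(0)
    mol_of_atom = np.concatenate(mol_of_atom)
    return BatchFeatures(
        z=z,
        rbf=_rbf_expand(d, config.num_rbf, config.cutoff),
        edge_src=ej,
        edge_plan=ScatterPlan(ei, n_atoms),
        src_plan=ScatterPlan(ej, n_atoms),
        pool_plan=ScatterPlan(mol_of_atom, len(molecules)),
        molecule_ids=[m.source_id for m in molecules],
    )


class Encoder:
    """Reference continuous-filter encoder with trainable numpy parameters."""

    def __init__(self, config: EncoderConfig):
        self.config = config
        self.frozen = False
        h, f, k = config.hidden_dim, config.num_filters, config.num_rbf
        p = max(len(config.output_properties), 1)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 211]))

        def uniform(*shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return parameter(rng.uniform(-bound, bound, size=shape))

        self.params: dict[str, Tensor] = {
            "embedding": uniform(config.z_max + 1, h, fan_in=h)
        }
        for t in range(config.num_interactions):
            self.params[f"int{t}.filter_w1"] = uniform(k, f, fan_in=k)
            self.params[f"int{t}.filter_b1"] = parameter(np.zeros(f))
            self.params[f"int{t}.filter_w2"] = uniform(f, f, fan_in=f)
            self.params[f"int{t}.filter_b2"] = parameter(np.zeros(f))
            self.params[f"int{t}.in_w"] = uniform(h, f, fan_in=h)
            self.params[f"int{t}.out_w1"] = uniform(f, h, fan_in=f)
            self.params[f"int{t}.out_b1"] = parameter(np.zeros(h))
            self.params[f"int{t}.out_w2"] = uniform(h, h, fan_in=h)
            self.params[f"int{t}.out_b2"] = parameter(np.zeros(h))
        self.params["head_w"] = uniform(h, p, fan_in=h)
        self.params["head_b"] = parameter(np.zeros(p))

    # -- state -------------------------------------------------------------
    def freeze(self) -> "Encoder":
        self.frozen = True
        for p in self.params.values():
            p.requires_grad = False
        return self

    def trainable_parameters(self) -> list[Tensor]:
        return [] if self.frozen else list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            if k not in arrays or arrays[k].shape != v.data.shape:
                raise ValueError(f"checkpoint mismatch for parameter {k!r}")
            v.data = arrays[k].astype(np.float64).copy()

    def checksum(self) -> float:
        return float(sum(np.abs(v.data).sum() for v in self.params.values()))

    # -- forward -----------------------------------------------------------
    def forward(self, feats: BatchFeatures) -> tuple[Tensor, Tensor]:
        """Return (molecular embeddings (n,H), predictions (n,P)) tensors."""
        cfg = self.config
        x = self.params["embedding"].take_rows(feats.z)
        rbf = constant(feats.rbf)
        for t in range(cfg.num_interactions):
            w = (
                (rbf @ self.params[f"int{t}.filter_w1"] + self.params[f"int{t}.filter_b1"])
                .ssp()
                @ self.params[f"int{t}.filter_w2"]
                + self.params[f"int{t}.filter_b2"]
            )
            # map atom states first (cheaper), then gather per edge
            neigh = gather_rows(
                x @ self.params[f"int{t}.in_w"], feats.edge_src, feats.src_plan
            )
            agg = segment_sum(w * neigh, feats.edge_plan)
            upd = (
                (agg @ self.params[f"int{t}.out_w1"] + self.params[f"int{t}.out_b1"])
                .ssp()
                @ self.params[f"int{t}.out_w2"]
                + self.params[f"int{t}.out_b2"]
            )
            x = x + upd
        emb = segment_sum(x, feats.pool_plan)
        pred = emb @ self.params["head_w"] + self.params["head_b"]
        return emb, pred


def build_encoder(config: EncoderConfig) -> Encoder:
    """Construct a seeded reference encoder from its config."""
    if config.family not in ("reference-cfconv", "plugin"):
        raise ValueError(f"unknown encoder family {config.family!r}")
    return Encoder(config)


def encode(encoder: Encoder, molecules: list[Molecule3D],
           producer: str = "teacher") -> EmbeddingMatrix:
    """Embed a batch: one row per molecule at the post-pooling layer."""
    if not molecules:
        return EmbeddingMatrix(
            np.zeros((0, encoder.config.hidden_dim)), [], producer
        )
    feats = featurize(molecules, encoder.config)
    emb, _ = encoder.forward(feats)
    if not np.all(np.isfinite(emb.data)):
        bad = int(np.argwhere(~np.isfinite(emb.data))[0][0])
        raise FloatingPointError(
            f"non-finite embedding for molecule {feats.molecule_ids[bad]}"
        )
    return EmbeddingMatrix(emb.data, feats.molecule_ids, producer)


def predict(encoder: Encoder, embeddings: EmbeddingMatrix) -> np.ndarray:
    """Apply the affine property head to precomputed embeddings."""
    w = encoder.params["head_w"].data
    if embeddings.dim != w.shape[0]:
        raise ValueError(
            f"embedding width {embeddings.dim} does not match head input {w.shape[0]}"
        )
    return embeddings.values @ w + encoder.params["head_b"].data


def make_student_family(
    teacher_config: EncoderConfig, family: str, sizes: list[int]
) -> list[EncoderConfig]:
    """Configs for a capacity sweep along filters (F) or blocks (T).

    Mirrors the published reductions: filters 128 → {8, 16, 32, 64} and
    interaction blocks 4 → {1, 2, 3}. Embedding width H is untouched, so
    teacher/student cosines need no projection.
    """
    if family not in ("filters", "blocks"):
        raise ValueError(f"unknown student family {family!r}")
    if list(sizes) != sorted(set(sizes)):
        raise ValueError("sizes must be strictly increasing")
    attr = "num_filters" if family == "filters" else "num_interactions"
    teacher_value = getattr(teacher_config, attr)
    for s in sizes:
        if s >= teacher_value:
            raise ValueError(
                f"student {attr}={s} must be smaller than teacher's {teacher_value}"
            )
    return [replace(teacher_config, **{attr: s}) for s in sizes]


def count_parameters(encoder: Encoder) -> int:
    """Number of trainable scalars (0 once the encoder is frozen)."""
    if encoder.frozen:
        return 0
    return int(sum(v.data.size for v in encoder.params.values()))


def save_encoder(encoder: Encoder, path: str) -> None:
    """Single-archive checkpoint: config JSON + parameter arrays."""
    cfg = encoder.config.__dict__.copy()
    cfg["output_properties"] = list(cfg["output_properties"])
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(cfg))
        buf = io.BytesIO()
        np.savez(buf, **encoder.state_arrays())
        zf.writestr("params.npz", buf.getvalue())


def load_encoder(path: str) -> Encoder:
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        cfg["output_properties"] = tuple(cfg["output_properties"])
        config = EncoderConfig(**cfg)
        enc = build_encoder(config)
        with zf.open("params.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    enc.load_state(arrays)
    return enc
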