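"""Training-data attribution by encoder latent-space similarity.

Every reaction input is mapped to a fixed-length vector by mean-pooling
the final encoder states over its tokens.  The training reactions most
similar to a query — according to the model, not to any fingerprint — are
the nearest rows of the pooled-state matrix under the score

    score(u, v) = 1 / (1 + ||u - v||),

a monotone transform of Euclidean distance into (0, 1].  Retrieval is an
exact brute-force scan: desk-scale indexes are small and exactness keeps
the method trivially checkable against exhaustive scoring.

The index persists as a row-major float32 binary alongside a JSON sidecar
(ids, width, and a fingerprint of the producing model, so that an index
is never queried with vectors from a different model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import TransformerPredictor
from .reaction_io import ReactionRecord, source_string, tokenize_smiles

__all__ = [
    "LatentVector",
    "LatentIndex",
    "ModelMismatchError",
    "encode_reaction",
    "build_index",
    "similarity_score",
    "top_n_similar",
    "save_index",
    "load_index",
]


class ModelMismatchError(ValueError):
    """Index and query were produced by different models."""


@dataclass(frozen=True)
class LatentVector:
    """Mean-pooled encoder state of one reaction input."""

    values: np.ndarray
    reaction_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent vector has non-finite entries")


@dataclass
class LatentIndex:
    """M x d matrix of training-reaction latents with ids and provenance."""

    matrix: np.ndarray
    ids: list[str]
    model_fingerprint: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")

    def __len__(self) -> int:
        return self.matrix.shape[0]


def encode_reaction(model: TransformerPredictor, source) -> LatentVector:
    """Arithmetic mean of the final encoder states over all source tokens.

    Every token participates — reagents and separators included.
    """
    states = model.encoder_states(source)
    if states.shape[0] == 0:
        raise ValueError("cannot encode an empty token sequence")
    return LatentVector(values=states.mean(axis=0))


def build_index(model: TransformerPredictor, corpus) -> LatentIndex:
    """One latent row per training reaction, in corpus order."""
    rows, ids = [], []
    for record in corpus:
        src = tokenize_smiles(source_string(record))
        rows.append(encode_reaction(model, src).values)
        ids.append(record.id)
    return LatentIndex(
        matrix=np.vstack(rows).astype(np.float32),
        ids=ids,
        model_fingerprint=model.fingerprint(),
    )


def similarity_score(u, v) -> float:
    """1 / (1 + Euclidean distance); in (0, 1], symmetric, 1 iff u == v."""
    a = u.values if isinstance(u, LatentVector) else np.asarray(u, dtype=float)
    b = v.values if isinstance(v, LatentVector) else np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return 1.0 / (1.0 + float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float))))


def top_n_similar(
    query: LatentVector,
    index: LatentIndex,
    n: int,
    model_fingerprint: str | None = None,
) -> list[tuple[str, float]]:
    """The n most similar training reactions, best first.

    Ties break by corpus order.  If ``n`` exceeds the index size, all rows
    are returned (with a warning).  Passing the querying model's
    fingerprint enforces that index and query come from the same model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model_fingerprint is not None and model_fingerprint != index.model_fingerprint:
        raise ModelMismatchError(
            "index was built by a different model than the query encoder"
        )
    if n > len(index):
        import warnings

        warnings.warn(
            f"n={n} exceeds index size {len(index)}; returning all rows",
            stacklevel=2,
        )
        n = len(index)
    q = np.asarray(query.values, dtype=np.float64)
    d = np.linalg.norm(index.matrix.astype(np.float64) - q, axis=1)
    scores = 1.0 / (1.0 + d)
    # stable sort on -score preserves corpus order among ties
    order = np.argsort(-scores, kind="stable")[:n]
    return [(index.ids[i], float(scores[i])) for i in order]


def save_index(index: LatentIndex, prefix) -> None:
    """Persist as ``<prefix>.f32`` (row-major float32) + ``<prefix>.json``."""
    prefix = Path(prefix)
    mat = np.ascontiguousarray(index.matrix, dtype=np.float32)
    mat.tofile(f"{prefix}.f32")
    sidecar = {
        "ids": index.ids,
        "rows": int(mat.shape[0]),
        "width": int(mat.shape[1]),
        "dtype": "float32",
        "model_fingerprint": index.model_fingerprint,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar))


def load_index(prefix) -> LatentIndex:
    sidecar = json.loads(Path(f"{prefix}.json").read_text())
    mat = np.fromfile(f"{prefix}.f32", dtype=np.float32).reshape(
        sidecar["rows"], sidecar["width"]
    )
    return LatentIndex(
        matrix=mat,
        ids=list(sidecar["ids"]),
        model_fingerprint=sidecar["model_fingerprint"],
    )
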