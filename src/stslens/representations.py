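"""Fixed-size pair representations from layer-wise token vectors.

Each layer of a transformer yields one vector per token of the encoded
pair.  Ten pooling schemes map that variable-length list to a fixed-size
representation of the pair: the classification-token vector, mean/max
pools of each sentence and their concatenations or absolute differences,
the grand mean over all tokens, and the cosine distance between the two
sentences' pooled vectors.

Sentence spans exclude the [CLS]/[SEP] positions; ``avg_representation``
averages over *all* token positions including the special tokens.
Cosine distance is 1 - cosine similarity (range [0, 2]); a zero-norm
pooled operand raises rather than silently returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np

from .data import (
    ActivationSet,
    SEGMENT_A,
    SEGMENT_B,
    SEGMENT_CLS,
    SEGMENT_SEP,
    ValidationError,
)

#: the ten representation names, in canonical order
REPRESENTATION_NAMES = (
    "cls",
    "avg_reps_concat",
    "max_reps_concat",
    "sent_avg_difference",
    "sent_max_difference",
    "sent_a_avg_max_concat",
    "sent_b_avg_max_concat",
    "avg_representation",
    "avg_sent_cosine_dist",
    "max_sent_cosine_dist",
)

#: representations whose value is a scalar rather than a vector
SCALAR_REPRESENTATIONS = ("avg_sent_cosine_dist", "max_sent_cosine_dist")


def representation_dim(rep_name: str, hidden_dim: int) -> int:
    """Output dimension of a representation (1 for the scalar distances)."""
    if rep_name in ("cls", "sent_avg_difference", "sent_max_difference",
                    "avg_representation"):
        return hidden_dim
    if rep_name in ("avg_reps_concat", "max_reps_concat",
                    "sent_a_avg_max_concat", "sent_b_avg_max_concat"):
        return 2 * hidden_dim
    if rep_name in SCALAR_REPRESENTATIONS:
        return 1
    raise ValidationError(f"unknown representation {rep_name!r}")


@dataclass(frozen=True)
class SegmentSpans:
    cls: int
    a: tuple[int, ...]
    b: tuple[int, ...]


def segment_spans(segments: Sequence[str]) -> SegmentSpans:
    """Positions of the [CLS] token and of each sentence's own tokens.

    Works for both input layouts ([CLS] first, BERT-style, or [CLS]
    last, XLNet-style); the A/B spans never include special tokens.
    """
    cls_positions = [i for i, s in enumerate(segments) if s == SEGMENT_CLS]
    sep_positions = [i for i, s in enumerate(segments) if s == SEGMENT_SEP]
    if len(cls_positions) != 1:
        raise ValidationError(
            f"expected exactly one CLS label, found {len(cls_positions)}"
        )
    if len(sep_positions) != 2:
        raise ValidationError(
            f"expected exactly two SEP labels, found {len(sep_positions)}"
        )
    a = tuple(i for i, s in enumerate(segments) if s == SEGMENT_A)
    b = tuple(i for i, s in enumerate(segments) if s == SEGMENT_B)
    known = {SEGMENT_A, SEGMENT_B, SEGMENT_CLS, SEGMENT_SEP}
    bad = [s for s in segments if s not in known]
    if bad:
        raise ValidationError(f"unknown segment labels {sorted(set(bad))}")
    if not a or not b:
        raise ValidationError("both sentence spans must be non-empty")
    return SegmentSpans(cls=cls_positions[0], a=a, b=b)


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("cosine distance undefined for zero-norm vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def build_representation(
    layer_matrix: np.ndarray, spans: SegmentSpans, rep_name: str
) -> np.ndarray:
    """One pair representation from a (n_tokens, dim) layer matrix.

    Vector representations return a 1-d array; the cosine distances
    return a length-1 array so downstream code can treat every
    representation as a feature vector.
    """
    X = np.asarray(layer_matrix, dtype=float)
    a, b = X[list(spans.a)], X[list(spans.b)]
    if rep_name == "cls":
        return X[spans.cls].copy()
    if rep_name == "avg_reps_concat":
        return np.concatenate([a.mean(axis=0), b.mean(axis=0)])
    if rep_name == "max_reps_concat":
        return np.concatenate([a.max(axis=0), b.max(axis=0)])
    if rep_name == "sent_avg_difference":
        return np.abs(a.mean(axis=0) - b.mean(axis=0))
    if rep_name == "sent_max_difference":
        return np.abs(a.max(axis=0) - b.max(axis=0))
    if rep_name == "sent_a_avg_max_concat":
        return np.concatenate([a.mean(axis=0), a.max(axis=0)])
    if rep_name == "sent_b_avg_max_concat":
        return np.concatenate([b.mean(axis=0), b.max(axis=0)])
    if rep_name == "avg_representation":
        return X.mean(axis=0)
    if rep_name == "avg_sent_cosine_dist":
        return np.array([cosine_distance(a.mean(axis=0), b.mean(axis=0))])
    if rep_name == "max_sent_cosine_dist":
        return np.array([cosine_distance(a.max(axis=0), b.max(axis=0))])
    raise ValidationError(f"unknown representation {rep_name!r}")


@dataclass
class RepresentationTable:
    """Representations for one model: (rep, layer) -> (n_pairs, dim) matrix.

    ``pair_ids`` fixes the row order shared by every matrix.
    """

    model_name: str
    hidden_dim: int
    pair_ids: list[str]
    values: dict[tuple[str, int], np.ndarray]

    def matrix(self, rep_name: str, layer: int) -> np.ndarray:
        return self.values[(rep_name, layer)]

    @property
    def layers(self) -> list[int]:
        return sorted({layer for _, layer in self.values})

    @property
    def rep_names(self) -> list[str]:
        seen = {rep for rep, _ in self.values}
        return [r for r in REPRESENTATION_NAMES if r in seen]


def build_all(
    activations: ActivationSet,
    layers: Iterable[int],
    reps: Sequence[str] = REPRESENTATION_NAMES,
) -> RepresentationTable:
    """Every requested representation at every requested layer.

    Rows are ordered by pair_id; errors are re-raised with the offending
    pair named.
    """
    layers = sorted(set(int(l) for l in layers))
    bad_layers = [l for l in layers if not 1 <= l <= activations.model.n_layers]
    if bad_layers:
        raise ValidationError(
            f"layers {bad_layers} outside 1..{activations.model.n_layers}"
        )
    for rep in reps:
        representation_dim(rep, activations.model.hidden_dim)  # validates name

    pair_ids = activations.pair_ids
    values: dict[tuple[str, int], np.ndarray] = {}
    spans = {
        pid: segment_spans(activations.pairs[pid].segments) for pid in pair_ids
    }
    for layer in layers:
        for rep in reps:
            rows = []
            for pid in pair_ids:
                try:
                    rows.append(
                        build_representation(
                            activations.pairs[pid].layer(layer), spans[pid], rep
                        )
                    )
                except ValidationError as err:
                    raise ValidationError(f"pair {pid}: {err}") from err
            values[(rep, layer)] = np.vstack(rows)
    return RepresentationTable(
        model_name=activations.model.name,
        hidden_dim=activations.model.hidden_dim,
        pair_ids=list(pair_ids),
        values=values,
    )


def write_representations_h5(table: RepresentationTable, path) -> None:
    """HDF5 layout: /<model>/<rep_name>/layer_NN, rows ordered by pair_id."""
    with h5py.File(path, "w") as f:
        grp = f.create_group(table.model_name)
        grp.attrs["pair_ids"] = np.array(table.pair_ids, dtype="S64")
        grp.attrs["hidden_dim"] = table.hidden_dim
        for (rep, layer), mat in sorted(table.values.items()):
            rg = grp.require_group(rep)
            rg.create_dataset(
                f"layer_{layer:02d}",
                data=mat.astype(np.float32),
                track_times=False,
            )


def read_representations_h5(path, model_name: str | None = None) -> RepresentationTable:
    with h5py.File(path, "r") as f:
        names = list(f)
        if model_name is None:
            if len(names) != 1:
                raise ValidationError(
                    f"file holds models {names}; specify model_name"
                )
            model_name = names[0]
        grp = f[model_name]
        pair_ids = [s.decode() for s in grp.attrs["pair_ids"]]
        hidden_dim = int(grp.attrs["hidden_dim"])
        values = {}
        for rep in grp:
            for dset in grp[rep]:
                layer = int(dset.split("_")[1])
                values[(rep, layer)] = grp[rep][dset][()].astype(float)
    return RepresentationTable(
        model_name=model_name,
        hidden_dim=hidden_dim,
        pair_ids=pair_ids,
        values=values,
    )
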