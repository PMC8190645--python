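"""Core domain containers and on-disk formats.

The item unit throughout the package is the sentence *pair*: two token
sequences and a gold semantic-similarity score on the 0-5 scale used by
clinical STS corpora.  Activations are the layer-wise token vectors a
transformer produces while encoding a pair, stored per pair as a
``(n_layers, n_tokens, hidden_dim)`` array together with a segment label
(CLS / A / SEP / B) for every token position.

On-disk formats:

* pairs / predictions: UTF-8 TSV with a header row,
* activations: HDF5, one group per ``/<model>/<pair_id>`` holding
  ``layer_01 .. layer_NN`` float32 datasets plus ``segments``, ``layout``
  and ``hidden_dim`` attributes.

All HDF5 datasets are written with ``track_times=False`` so regenerating
with the same seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

MAX_SEQUENCE_LENGTH = 128
#: token budget for the two sentences: 3 positions are reserved for the
#: special tokens ([CLS] and two [SEP]s)
MAX_PAIR_TOKENS = 125

SEGMENT_CLS = "CLS"
SEGMENT_SEP = "SEP"
SEGMENT_A = "A"
SEGMENT_B = "B"

LAYOUT_CLS_FIRST = "cls_first"  # [CLS] A [SEP] B [SEP]  (BERT-style)
LAYOUT_CLS_LAST = "cls_last"    # A [SEP] B [SEP] [CLS]  (XLNet-style)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class SentencePair:
    """A sentence pair with its gold similarity score (0-5)."""

    pair_id: str
    tokens_a: tuple[str, ...]
    tokens_b: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if not self.tokens_a or not self.tokens_b:
            raise ValidationError(f"{self.pair_id}: empty sentence")
        if not (0.0 <= self.score <= 5.0):
            raise ValidationError(
                f"{self.pair_id}: score {self.score} outside [0, 5]"
            )
        if len(self.tokens_a) + len(self.tokens_b) > MAX_PAIR_TOKENS:
            raise ValidationError(
                f"{self.pair_id}: {len(self.tokens_a) + len(self.tokens_b)} "
                f"tokens exceed the {MAX_PAIR_TOKENS}-token pair budget"
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens_a) + len(self.tokens_b)


@dataclass
class Corpus:
    """Train/test sentence pairs plus the train-split token counts."""

    train: list[SentencePair]
    test: list[SentencePair]
    vocab: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.vocab:
            self.vocab = count_tokens(self.train)

    def validate(self) -> None:
        if self.vocab != count_tokens(self.train):
            raise ValidationError("vocab counts do not match train sentences")


def count_tokens(pairs: Iterable[SentencePair]) -> dict[str, int]:
    """Token counts over both sentences of every pair (duplicates counted)."""
    counts: dict[str, int] = {}
    for pair in pairs:
        for tok in pair.tokens_a + pair.tokens_b:
            counts[tok] = counts.get(tok, 0) + 1
    return counts


@dataclass(frozen=True)
class ModelSpec:
    """Shape and input layout of a (virtual) transformer model."""

    name: str
    n_layers: int
    hidden_dim: int
    layout: str = LAYOUT_CLS_FIRST

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValidationError("n_layers and hidden_dim must be >= 1")
        if self.layout not in (LAYOUT_CLS_FIRST, LAYOUT_CLS_LAST):
            raise ValidationError(f"unknown layout {self.layout!r}")


def segment_labels(len_a: int, len_b: int, layout: str) -> tuple[str, ...]:
    """Per-position segment labels for a pair under the given input layout."""
    a = (SEGMENT_A,) * len_a
    b = (SEGMENT_B,) * len_b
    if layout == LAYOUT_CLS_FIRST:
        return (SEGMENT_CLS,) + a + (SEGMENT_SEP,) + b + (SEGMENT_SEP,)
    if layout == LAYOUT_CLS_LAST:
        return a + (SEGMENT_SEP,) + b + (SEGMENT_SEP,) + (SEGMENT_CLS,)
    raise ValidationError(f"unknown layout {layout!r}")


@dataclass
class PairActivations:
    """Layer-wise token vectors for one pair: (n_layers, n_tokens, dim)."""

    pair_id: str
    tensor: np.ndarray
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3:
            raise ValidationError("activation tensor must be 3-d")
        if self.tensor.shape[1] != len(self.segments):
            raise ValidationError("segment labels must match token count")
        if self.tensor.shape[1] > MAX_SEQUENCE_LENGTH:
            raise ValidationError(
                f"{self.tensor.shape[1]} tokens exceed max sequence "
                f"length {MAX_SEQUENCE_LENGTH}"
            )
        if self.segments.count(SEGMENT_CLS) != 1:
            raise ValidationError("exactly one CLS position required")
        if self.segments.count(SEGMENT_SEP) != 2:
            raise ValidationError("exactly two SEP positions required")

    def layer(self, layer_index: int) -> np.ndarray:
        """Token matrix of a 1-indexed layer (layer 1 = first block output)."""
        return self.tensor[layer_index - 1]


@dataclass
class ActivationSet:
    """All pairs' activations for one model."""

    model: ModelSpec
    pairs: dict[str, PairActivations]

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.pairs)


@dataclass
class PredictionSet:
    """Per-pair predicted similarity scores for one model."""

    model_name: str
    predictions: dict[str, float]

    def aligned(self, pair_ids: Iterable[str]) -> np.ndarray:
        ids = list(pair_ids)
        missing = [i for i in ids if i not in self.predictions]
        if missing:
            raise ValidationError(
                f"{self.model_name}: missing predictions for {missing[:5]}"
            )
        return np.array([self.predictions[i] for i in ids], dtype=float)


# ---------------------------------------------------------------------------
# TSV round-trips


def pairs_to_frame(pairs: Iterable[SentencePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "sentence_a": [" ".join(p.tokens_a) for p in pairs],
            "sentence_b": [" ".join(p.tokens_b) for p in pairs],
            "score": [p.score for p in pairs],
        }
    )


def write_pairs_tsv(pairs: Iterable[SentencePair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[SentencePair]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    return [
        SentencePair(
            pair_id=row.pair_id,
            tokens_a=tuple(row.sentence_a.split()),
            tokens_b=tuple(row.sentence_b.split()),
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]


def write_predictions_tsv(predsets: Iterable[PredictionSet], path) -> None:
    rows = []
    for ps in predsets:
        for pair_id in sorted(ps.predictions):
            rows.append((pair_id, ps.model_name, ps.predictions[pair_id]))
    pd.DataFrame(rows, columns=["pair_id", "model_name", "prediction"]).to_csv(
        path, sep="\t", index=False
    )


def read_predictions_tsv(path) -> dict[str, PredictionSet]:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "model_name": str})
    out: dict[str, PredictionSet] = {}
    for name, grp in df.groupby("model_name", sort=True):
        out[str(name)] = PredictionSet(
            model_name=str(name),
            predictions=dict(zip(grp.pair_id, grp.prediction.astype(float))),
        )
    return out


# ---------------------------------------------------------------------------
# HDF5 round-trip for activations


def write_activations_h5(acts: ActivationSet, path) -> None:
    with h5py.File(path, "w", track_order=False) as f:
        grp = f.create_group(acts.model.name)
        grp.attrs["n_layers"] = acts.model.n_layers
        grp.attrs["hidden_dim"] = acts.model.hidden_dim
        grp.attrs["layout"] = acts.model.layout
        for pair_id in acts.pair_ids:
            pa = acts.pairs[pair_id]
            pg = grp.create_group(pair_id)
            pg.attrs["segments"] = np.array(pa.segments, dtype="S8")
            pg.attrs["layout"] = acts.model.layout
            pg.attrs["hidden_dim"] = acts.model.hidden_dim
            for li in range(acts.model.n_layers):
                pg.create_dataset(
                    f"layer_{li + 1:02d}",
                    data=pa.tensor[li].astype(np.float32),
                    track_times=False,
                )


def read_activations_h5(path, model_name: str | None = None) -> ActivationSet:
    with h5py.File(path, "r") as f:
        names = list(f)
        if model_name is None:
            if len(names) != 1:
                raise ValidationError(
                    f"file holds models {names}; specify model_name"
                )
            model_name = names[0]
        grp = f[model_name]
        spec = ModelSpec(
            name=model_name,
            n_layers=int(grp.attrs["n_layers"]),
            hidden_dim=int(grp.attrs["hidden_dim"]),
            layout=str(grp.attrs["layout"]),
        )
        pairs: dict[str, PairActivations] = {}
        for pair_id in grp:
            pg = grp[pair_id]
            segs = tuple(s.decode() for s in pg.attrs["segments"])
            tensor = np.stack(
                [pg[f"layer_{li + 1:02d}"][()] for li in range(spec.n_layers)]
            )
            pairs[pair_id] = PairActivations(pair_id, tensor, segs)
    return ActivationSet(model=spec, pairs=pairs)
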