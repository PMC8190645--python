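"""Synthetic clinical-STS stand-ins with planted, recoverable structure.

The real corpus this package was designed around (clinical sentence
pairs scored 0-5 by medical experts) is access-restricted, and the
transformer activations analysed downstream require GPU fine-tuning.
This module generates substitutes with the same shapes and, crucially,
with *known* structure planted into them, so that every downstream stage
— surface-feature error analysis, linear probing, RSA reweighting — can
be validated as a recovery problem:

* ``generate_corpus`` draws token sequences from a Zipf-skewed synthetic
  vocabulary (plus a fixed stop-word list) and couples token overlap to
  the gold score, so the Jaccard/score relationship is plantable.
* ``generate_predictions`` emulates a similarity model that over-relies
  on token overlap: predictions are the gold score plus an additive
  bias, an overlap-tracking bias, and Gaussian noise, clipped to [0, 5].
* ``generate_activations`` fills layer-wise token tensors with Gaussian
  noise and surgically plants a score encoding into any chosen
  (layer, representation) cell, exactly recoverable by the probing and
  RSA modules.

Sentences are token sequences, not grammatical clinical text, and no
subword tokenizer is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import (
    ActivationSet,
    Corpus,
    LAYOUT_CLS_FIRST,
    MAX_PAIR_TOKENS,
    ModelSpec,
    PairActivations,
    PredictionSet,
    SentencePair,
    ValidationError,
    segment_labels,
)
from .features import jaccard_distance
from .representations import (
    REPRESENTATION_NAMES,
    SCALAR_REPRESENTATIONS,
    segment_spans,
)
from .seeding import rng_for
from .stopwords import DEFAULT_STOPWORDS

DEFAULT_SCORE_LEVELS = tuple(np.arange(0.0, 5.01, 0.5))


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the synthetic corpus.

    Defaults mirror the clinical STS setting the package emulates:
    1642 train / 412 test pairs, half-point score levels on [0, 5], a
    Zipf-skewed vocabulary of 2000 content types, and an overlap
    coupling that makes higher-scoring pairs share more tokens.
    """

    n_train: int = 1642
    n_test: int = 412
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    score_levels: tuple[float, ...] = DEFAULT_SCORE_LEVELS
    overlap_coupling: float = 0.7
    overlap_jitter: float = 0.15
    min_sentence_len: int = 6
    max_sentence_len: int = 18
    stopword_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValidationError("corpus sizes must be positive")
        if not self.score_levels:
            raise ValidationError("score_levels must be non-empty")
        if not 0.0 <= self.overlap_coupling <= 1.0:
            raise ValidationError("overlap_coupling must lie in [0, 1]")
        if any(not 0.0 <= s <= 5.0 for s in self.score_levels):
            raise ValidationError("score levels must lie in [0, 5]")
        if 2 * self.max_sentence_len > MAX_PAIR_TOKENS:
            raise ValidationError("max_sentence_len exceeds the pair budget")


def _zipf_weights(vocab_size: int, exponent: float) -> np.ndarray:
    w = np.arange(1, vocab_size + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _draw_sentence(
    rng: np.random.Generator,
    length: int,
    content_types: np.ndarray,
    weights: np.ndarray,
    stoplist: tuple[str, ...],
    stopword_rate: float,
) -> list[str]:
    is_stop = rng.random(length) < stopword_rate
    content = rng.choice(content_types, size=length, p=weights)
    stops = rng.choice(np.array(stoplist), size=length)
    return [str(stops[i]) if is_stop[i] else str(content[i]) for i in range(length)]


def _generate_pair(
    rng: np.random.Generator,
    pair_id: str,
    config: CorpusConfig,
    content_types: np.ndarray,
    weights: np.ndarray,
    stoplist: tuple[str, ...],
) -> SentencePair:
    score = float(rng.choice(np.asarray(config.score_levels)))
    len_a = int(rng.integers(config.min_sentence_len, config.max_sentence_len + 1))
    len_b = int(rng.integers(config.min_sentence_len, config.max_sentence_len + 1))
    tokens_a = _draw_sentence(
        rng, len_a, content_types, weights, stoplist, config.stopword_rate
    )
    # overlap planting: copy a score-dependent fraction of A's tokens into B.
    # The jitter gives each score level a spread of overlaps, emulating real
    # corpora where some dissimilar pairs overlap heavily and some
    # near-identical pairs are paraphrases with little shared vocabulary.
    frac = config.overlap_coupling * score / 5.0
    if config.overlap_jitter > 0:
        frac = float(np.clip(frac + rng.normal(0.0, config.overlap_jitter), 0.0, 1.0))
    n_copy = int(round(frac * len_b))
    copied: list[str]
    if n_copy >= len_a:
        # cycle through A so a fully-coupled pair shares its whole token set
        copied = [tokens_a[j % len_a] for j in range(n_copy)]
    else:
        idx = rng.choice(len_a, size=n_copy, replace=False)
        copied = [tokens_a[i] for i in sorted(idx)]
    fresh = _draw_sentence(
        rng, len_b - n_copy, content_types, weights, stoplist, config.stopword_rate
    )
    tokens_b = copied + fresh
    if n_copy < len_b:
        perm = rng.permutation(len_b)
        tokens_b = [tokens_b[i] for i in perm]
    return SentencePair(
        pair_id=pair_id,
        tokens_a=tuple(tokens_a),
        tokens_b=tuple(tokens_b),
        score=score,
    )


def generate_corpus(config: CorpusConfig, seed: int) -> Corpus:
    """A deterministic synthetic corpus.

    Pairs with higher gold scores share a larger expected fraction of
    tokens, scaled by ``overlap_coupling``; at coupling 1 a score-5 pair
    repeats sentence A's tokens verbatim.  Vocabulary counts are built
    from the train split only.
    """
    content_types = np.array(
        [f"w{i:04d}" for i in range(config.vocab_size)], dtype=object
    )
    weights = _zipf_weights(config.vocab_size, config.zipf_exponent)
    stoplist = tuple(sorted(DEFAULT_STOPWORDS))

    def make_split(split: str, n: int) -> list[SentencePair]:
        pairs = []
        for i in range(n):
            rng = rng_for(seed, "corpus", split, i)
            pairs.append(
                _generate_pair(
                    rng, f"{split}_{i:05d}", config, content_types, weights, stoplist
                )
            )
        return pairs

    return Corpus(
        train=make_split("train", config.n_train),
        test=make_split("test", config.n_test),
    )


# ---------------------------------------------------------------------------
# biased predictions


@dataclass(frozen=True)
class BiasConfig:
    """Controllable biases of a simulated similarity model.

    ``overlap_bias_strength`` reproduces the over-reliance on token
    overlap that error analyses diagnose in real similarity models:
    the prediction is pushed up for high-overlap pairs and down for
    low-overlap pairs, relative to the mean overlap, before clipping
    to [0, 5].
    """

    overlap_bias_strength: float = 1.0
    additive_bias: float = 0.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate_predictions(
    corpus: Corpus,
    bias: BiasConfig,
    seed: int,
    model_name: str = "synthetic_model",
) -> PredictionSet:
    """Biased predictions for every test pair, clipped to [0, 5]."""
    pairs = corpus.test
    overlaps = np.array(
        [1.0 - jaccard_distance(p.tokens_a, p.tokens_b) for p in pairs]
    )
    centering = overlaps.mean()
    rng = rng_for(seed, "predictions", model_name)
    noise = rng.normal(0.0, bias.noise_sd, size=len(pairs)) if bias.noise_sd else 0.0
    raw = (
        np.array([p.score for p in pairs])
        + bias.additive_bias
        + bias.overlap_bias_strength * (overlaps - centering)
        + noise
    )
    clipped = np.clip(raw, 0.0, 5.0)
    return PredictionSet(
        model_name=model_name,
        predictions={p.pair_id: float(v) for p, v in zip(pairs, clipped)},
    )


# ---------------------------------------------------------------------------
# activations with planted signal


@dataclass(frozen=True)
class Planting:
    """Plant a score encoding at one (layer, representation) cell.

    ``strength`` scales the encoding relative to the unit-variance
    background noise; ``noise_sd`` adds Gaussian jitter to the planted
    coefficient so recovery difficulty is controllable.  Vector
    representations receive a linear encoding of ``score - mean(score)``
    along a fixed random unit direction; the cosine-distance scalars
    receive an angle monotone in ``5 - score``.
    """

    layer: int
    rep_name: str
    strength: float
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rep_name not in REPRESENTATION_NAMES:
            raise ValidationError(f"unknown representation {self.rep_name!r}")
        if self.strength < 0 or self.noise_sd < 0:
            raise ValidationError("strength and noise_sd must be >= 0")


#: token positions a planted vector encoding is written into, per rep
_PLANT_SPAN = {
    "cls": "cls",
    "avg_reps_concat": "a",
    "max_reps_concat": "a",
    "sent_a_avg_max_concat": "a",
    "sent_b_avg_max_concat": "b",
    "avg_representation": "all",
}


def _plant_into_pair(
    tensor: np.ndarray,
    spans,
    planting: Planting,
    coeff: float,
    u: np.ndarray,
    u2: np.ndarray,
) -> None:
    """Mutate one pair's layer tensor so the target representation
    carries the planted coefficient exactly."""
    L = planting.layer - 1
    rep = planting.rep_name
    a_idx, b_idx = list(spans.a), list(spans.b)
    if rep in _PLANT_SPAN:
        where = _PLANT_SPAN[rep]
        if where == "cls":
            tensor[L, spans.cls] += coeff * u
        elif where == "a":
            tensor[L, a_idx] += coeff * u
        elif where == "b":
            tensor[L, b_idx] += coeff * u
        else:
            tensor[L] += coeff * u
        return
    if rep in ("sent_avg_difference", "sent_max_difference"):
        # target pooled difference (K + coeff)*|u|: elementwise-positive
        # coefficient, so the absolute value is exactly linear in coeff
        margin = 1.0 + 2.5 * planting.strength + 5.0 * planting.noise_sd
        target = (margin + coeff) * np.abs(u)
        pool = np.mean if rep == "sent_avg_difference" else np.max
        current = pool(tensor[L, a_idx], axis=0) - pool(tensor[L, b_idx], axis=0)
        tensor[L, a_idx] += target - current
        return
    if rep in SCALAR_REPRESENTATIONS:
        # place pooled A on u, pooled B at an angle monotone in (5-score)
        scale = max(planting.strength, 1e-6)
        theta = float(np.clip(coeff, 0.0, np.pi))
        pool = np.mean if rep == "avg_sent_cosine_dist" else np.max
        target_a = 10.0 * scale * u
        target_b = 10.0 * scale * (np.cos(theta) * u + np.sin(theta) * u2)
        tensor[L, a_idx] += target_a - pool(tensor[L, a_idx], axis=0)
        tensor[L, b_idx] += target_b - pool(tensor[L, b_idx], axis=0)
        return
    raise ValidationError(f"unknown representation {rep!r}")  # pragma: no cover


def generate_activations(
    corpus_pairs: Sequence[SentencePair],
    model: ModelSpec,
    plantings: Sequence[Planting] = (),
    seed: int = 0,
    background_sd: float = 1.0,
) -> ActivationSet:
    """Layer-wise token activations with optional planted score signals.

    Background vectors are iid Gaussian noise; each planting directive
    then adjusts the tokens feeding its target representation.  Constant
    shifts commute with both mean- and max-pooling, so the planted
    statistic is hit exactly.  Plantings on the same layer are applied
    in order and may interact; keep one planting per layer for clean
    recovery experiments.
    """
    for p in plantings:
        if not 1 <= p.layer <= model.n_layers:
            raise ValidationError(
                f"planted layer {p.layer} outside 1..{model.n_layers}"
            )

    scores = np.array([p.score for p in corpus_pairs])
    mean_score = scores.mean()

    # fixed random orthonormal directions per planting directive
    directions = []
    for k, p in enumerate(plantings):
        drng = rng_for(seed, "plant_dir", model.name, k)
        u = drng.normal(size=model.hidden_dim)
        u /= np.linalg.norm(u)
        v = drng.normal(size=model.hidden_dim)
        v -= u * (u @ v)
        v /= np.linalg.norm(v)
        directions.append((u, v))

    pairs: dict[str, PairActivations] = {}
    for i, sp in enumerate(corpus_pairs):
        rng = rng_for(seed, "activations", model.name, i)
        segs = segment_labels(len(sp.tokens_a), len(sp.tokens_b), model.layout)
        tensor = rng.normal(
            0.0, background_sd, size=(model.n_layers, len(segs), model.hidden_dim)
        )
        spans = segment_spans(segs)
        for k, planting in enumerate(plantings):
            prng = rng_for(seed, "plant_coeff", model.name, k, i)
            eta = prng.normal(0.0, planting.noise_sd) if planting.noise_sd else 0.0
            if planting.rep_name in SCALAR_REPRESENTATIONS:
                coeff = (np.pi / 2.0) * (1.0 - sp.score / 5.0) + eta
            else:
                coeff = planting.strength * (sp.score - mean_score) + eta
            _plant_into_pair(
                tensor, spans, planting, coeff, directions[k][0], directions[k][1]
            )
        pairs[sp.pair_id] = PairActivations(sp.pair_id, tensor, segs)
    return ActivationSet(model=model, pairs=pairs)
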