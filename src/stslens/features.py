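"""Surface features of sentence pairs and the loss/feature correlation table.

A regression model's squared-error loss on a pair is related to five
surface features of the pair — total length, train-corpus token
frequency (stop words removed), unseen-token rate, across-sentence
frequency difference, and the Jaccard distance between the two token
sets.  Correlating loss with each feature, overall and within each gold
score level, exposes the shallow heuristics a similarity model has
learned (e.g. over-predicting similarity given high token overlap).

Conventions, fixed here and documented in the methods note:

* ``avg_sentence_length`` is the *total* token count over both sentences
  (its historical name notwithstanding); pass ``halve_length=True`` to
  divide by two.
* Frequency features count occurrences over both token lists (duplicates
  included) after stop-word removal; the unseen-token feature and the
  Jaccard distance use all tokens.
* Spearman rho uses average ranks for ties; Bonferroni multiplies each
  raw p by (number of features) x (number of evaluated groups).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import SentencePair, ValidationError
from .stopwords import DEFAULT_STOPWORDS

FEATURE_NAMES = (
    "avg_sentence_length",
    "scaled_total_token_frequency",
    "scaled_unseen_tokens",
    "scaled_freq_difference",
    "jaccard_distance",
)

_PUNCT_RE = re.compile(f"[{re.escape(string.punctuation)}]")


def default_tokenizer(text: str) -> list[str]:
    """Lower-cased, punctuation-stripped whitespace tokenization."""
    return [t for t in _PUNCT_RE.sub(" ", text.lower()).split() if t]


def pair_loss(prediction: float, label: float) -> float:
    """Squared error between a predicted and a gold similarity score."""
    if not (0.0 <= prediction <= 5.0) or not (0.0 <= label <= 5.0):
        raise ValidationError(
            f"scores must lie in [0, 5]; got ({prediction}, {label})"
        )
    return float((prediction - label) ** 2)


def jaccard_distance(tokens_a: Sequence[str], tokens_b: Sequence[str]) -> float:
    """1 - |A n B| / |A u B| over the two token *sets*.

    Duplicates collapse: the distance is 0 for identical sets and 1 for
    disjoint ones.  Both lists empty is undefined and raises.
    """
    set_a, set_b = set(tokens_a), set(tokens_b)
    union = set_a | set_b
    if not union:
        raise ValidationError("jaccard distance undefined for two empty lists")
    return 1.0 - len(set_a & set_b) / len(union)


def compute_pair_features(
    pair: SentencePair,
    vocab: Mapping[str, int],
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    halve_length: bool = False,
) -> dict[str, float]:
    """The five surface features of one pair against train-split counts.

    ``vocab`` must be token counts built from the train split only; using
    test counts would leak the quantity the unseen-token feature measures.
    """
    all_tokens = list(pair.tokens_a) + list(pair.tokens_b)
    if not all_tokens:
        raise ValidationError(f"{pair.pair_id}: empty pair")
    total_len = len(all_tokens)
    length_feature = total_len / 2 if halve_length else total_len

    content_a = [t for t in pair.tokens_a if t not in stopwords]
    content_b = [t for t in pair.tokens_b if t not in stopwords]

    freq_a = sum(vocab.get(t, 0) for t in content_a)
    freq_b = sum(vocab.get(t, 0) for t in content_b)
    unseen = sum(1 for t in all_tokens if t not in vocab)

    return {
        "pair_id": pair.pair_id,
        "avg_sentence_length": float(length_feature),
        "scaled_total_token_frequency": (freq_a + freq_b) / total_len,
        "scaled_unseen_tokens": unseen / total_len,
        "scaled_freq_difference": abs(freq_a - freq_b) / total_len,
        "jaccard_distance": jaccard_distance(pair.tokens_a, pair.tokens_b),
    }


def feature_table(
    pairs: Iterable[SentencePair],
    vocab: Mapping[str, int],
    predictions: Mapping[str, float],
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
    halve_length: bool = False,
) -> pd.DataFrame:
    """Feature rows for each pair with loss and label columns filled in."""
    rows = []
    for pair in pairs:
        row = compute_pair_features(pair, vocab, stopwords, halve_length)
        row["label"] = pair.score
        row["loss"] = pair_loss(float(predictions[pair.pair_id]), pair.score)
        rows.append(row)
    return pd.DataFrame(rows)


def loss_feature_correlations(
    rows: pd.DataFrame,
    group_by_label: bool = True,
    features: Sequence[str] = FEATURE_NAMES,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Spearman rho between loss and each feature, overall and per label.

    Returns a long-format table with columns ``label`` (a score level or
    "All"), ``feature``, ``rho``, ``p_raw``, ``p_bonferroni`` and ``n``.
    Degenerate cells — groups below ``min_group_size``, or a constant
    feature or constant loss within a group — report NaN rather than 0.
    The Bonferroni factor is (features) x (groups actually evaluated).
    """
    groups: list[tuple[object, pd.DataFrame]] = [("All", rows)]
    if group_by_label:
        for level in sorted(rows["label"].unique()):
            groups.append((level, rows[rows["label"] == level]))

    evaluated = [g for g in groups if len(g[1]) >= min_group_size]
    n_tests = len(features) * len(evaluated)

    out = []
    for label, grp in groups:
        usable = len(grp) >= min_group_size
        loss = grp["loss"].to_numpy()
        for feat in features:
            rho, p = np.nan, np.nan
            if usable:
                x = grp[feat].to_numpy()
                if np.ptp(x) > 0 and np.ptp(loss) > 0:
                    rho, p = stats.spearmanr(x, loss)
            p_adj = min(1.0, p * n_tests) if np.isfinite(p) else np.nan
            out.append(
                {
                    "label": label,
                    "feature": feat,
                    "rho": rho,
                    "p_raw": p,
                    "p_bonferroni": p_adj,
                    "n": len(grp),
                }
            )
    return pd.DataFrame(out)
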