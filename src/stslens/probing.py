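"""Layer-wise linear decoding of pair representations.

For each (layer, representation) cell a linear regression is trained to
predict the gold similarity score from the pair representation, scored
by the Pearson correlation between pooled out-of-fold predictions and
the gold scores under seeded k-fold cross-validation (10 folds by
default).

The solver is minimum-norm least squares (pseudoinverse) with an
intercept.  Concatenated representations can have more dimensions than
there are test items, so ordinary normal equations are singular;
the minimum-norm solution is deterministic and regularization-free.
An optional ridge penalty is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .data import ValidationError
from .representations import RepresentationTable


def select_layers(n_layers: int) -> list[int]:
    """Layers to analyse for a model of the given depth.

    12-layer (or shallower) models use every layer; 24-layer models use
    every other layer so depths compare by relative position; any other
    depth falls back to an evenly spaced subset of at most 12 layers.
    """
    if n_layers < 1:
        raise ValidationError("n_layers must be >= 1")
    if n_layers <= 12:
        return list(range(1, n_layers + 1))
    if n_layers == 24:
        return list(range(2, 25, 2))
    return sorted(set(np.linspace(1, n_layers, 12).round().astype(int).tolist()))


def _fit_linear(
    X: np.ndarray, y: np.ndarray, ridge: float | None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimum-norm least squares with intercept via column/target centering.

    Returns (coefficients, intercept, training-mean of X).
    """
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    if ridge is None:
        beta, *_ = np.linalg.lstsq(Xc, y - y_mean, rcond=None)
    else:
        d = Xc.shape[1]
        beta = np.linalg.solve(
            Xc.T @ Xc + ridge * np.eye(d), Xc.T @ (y - y_mean)
        )
    return beta, float(y_mean), x_mean


def fit_probe_cv(
    features: np.ndarray,
    targets: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    ridge: float | None = None,
) -> tuple[np.ndarray, float]:
    """Cross-validated linear probe.

    Items are shuffled by ``seed`` and split into ``folds`` contiguous
    blocks; each block is predicted by a model fit on the rest.  Returns
    the pooled out-of-fold predictions and their Pearson correlation
    with the targets (NaN when the targets or the pooled predictions
    are constant — never 0).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(targets, dtype=float)
    if X.shape[1] == 0:
        raise ValidationError("feature matrix has zero columns")
    if X.shape[0] != y.shape[0]:
        raise ValidationError("features and targets differ in length")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValidationError("missing values in probe inputs")
    n = X.shape[0]
    if folds < 2 or folds > n:
        raise ValidationError(f"folds must lie in 2..{n}")

    oof = np.empty(n)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X):
        beta, y_mean, x_mean = _fit_linear(X[train_idx], y[train_idx], ridge)
        oof[test_idx] = (X[test_idx] - x_mean) @ beta + y_mean

    if np.ptp(y) == 0 or np.ptp(oof) == 0:
        return oof, float("nan")
    r, _ = stats.pearsonr(oof, y)
    return oof, float(r)


@dataclass(frozen=True)
class ProbeResult:
    model_name: str
    rep_name: str
    layer: int
    cv_pearson: float
    n_items: int
    folds: int
    seed: int


def decode_all(
    representations: RepresentationTable,
    targets: dict[str, float],
    folds: int = 10,
    seed: int = 0,
    ridge: float | None = None,
) -> pd.DataFrame:
    """Probe every (representation, layer) cell of one model.

    ``targets`` maps pair_id to gold score and must cover exactly the
    table's pair ids.
    """
    missing = [pid for pid in representations.pair_ids if pid not in targets]
    if missing:
        raise ValidationError(f"targets missing for pair ids {missing[:5]}")
    y = np.array([targets[pid] for pid in representations.pair_ids])
    rows = []
    for rep in representations.rep_names:
        for layer in representations.layers:
            if (rep, layer) not in representations.values:
                continue
            _, r = fit_probe_cv(
                representations.matrix(rep, layer), y, folds=folds,
                seed=seed, ridge=ridge,
            )
            rows.append(
                ProbeResult(
                    model_name=representations.model_name,
                    rep_name=rep,
                    layer=layer,
                    cv_pearson=r,
                    n_items=len(y),
                    folds=folds,
                    seed=seed,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def rank_top(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k probe results by cv_pearson, descending.

    Ties break deterministically by (model, representation, layer).
    """
    if results.empty:
        raise ValidationError("empty probe-result table")
    ranked = results.sort_values(
        by=["cv_pearson", "model_name", "rep_name", "layer"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ranked.head(min(k, len(ranked)))
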