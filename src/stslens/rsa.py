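"""Representational similarity analysis with NNLS reweighting.

An RDM (representational dissimilarity matrix) holds the pairwise
dissimilarity between all items under some representation.  Basic RSA
compares a candidate RDM with the ground-truth RDM (absolute score
differences) by Spearman correlation over the strictly-upper triangle.
Reweighted/recombined RSA fits a non-negative linear combination of
candidate RDMs to the target with NNLS under item-level
cross-validation, reporting fold-averaged weights normalized to sum
to 1 and the mean held-out Spearman correlation.

Conventions (the field's standard ones, fixed here):

* vector representations are compared by cosine distance, scalar
  representations and text features by absolute difference;
* all comparisons use the strictly-upper triangle, ties get average
  ranks;
* CV folds are defined over items; NNLS trains on train x train
  entries and is evaluated on entries involving a held-out item.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import KFold

from .data import ValidationError


@dataclass
class RDM:
    """Symmetric, zero-diagonal, non-negative dissimilarity matrix."""

    item_ids: list[str]
    matrix: np.ndarray
    source: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError(f"{self.source}: RDM must be square")
        if m.shape[0] != len(self.item_ids):
            raise ValidationError(f"{self.source}: item ids do not match matrix")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError(f"{self.source}: RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValidationError(f"{self.source}: RDM diagonal must be zero")
        if (m < -1e-10).any():
            raise ValidationError(f"{self.source}: RDM entries must be >= 0")
        self.matrix = np.clip((m + m.T) / 2.0, 0.0, None)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def triangle(self) -> np.ndarray:
        """Strictly-upper-triangle entries as a vector."""
        iu = np.triu_indices(self.n_items, k=1)
        return self.matrix[iu]


def ground_truth_rdm(item_ids: Sequence[str], scores: Sequence[float]) -> RDM:
    """|score_i - score_j| over all item pairs, in the given item order."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 2:
        raise ValidationError("ground-truth RDM needs at least 2 items")
    return RDM(
        item_ids=list(item_ids),
        matrix=np.abs(s[:, None] - s[None, :]),
        source="ground_truth",
    )


def representation_rdm(
    item_ids: Sequence[str],
    values: np.ndarray,
    metric: str = "cosine",
    source: str = "representation",
) -> RDM:
    """RDM from per-item vectors (cosine) or scalars (abs_diff)."""
    v = np.asarray(values, dtype=float)
    if metric == "cosine":
        if v.ndim != 2:
            raise ValidationError("cosine metric requires per-item vectors")
        norms = np.linalg.norm(v, axis=1)
        bad = np.where(norms == 0)[0]
        if bad.size:
            raise ValidationError(
                f"{source}: zero-norm vector for item {item_ids[bad[0]]!r}"
            )
        mat = squareform(pdist(v, metric="cosine"))
    elif metric == "abs_diff":
        v = v.ravel()
        mat = np.abs(v[:, None] - v[None, :])
    else:
        raise ValidationError(f"unknown RDM metric {metric!r}")
    # pdist can leave tiny negative round-off on identical vectors
    return RDM(item_ids=list(item_ids), matrix=np.clip(mat, 0.0, None), source=source)


def feature_rdm(
    item_ids: Sequence[str], feature_values: Sequence[float], name: str
) -> RDM:
    """Absolute-difference RDM of a scalar text feature.

    A constant feature yields the all-zero RDM with ``degenerate=True``.
    """
    v = np.asarray(feature_values, dtype=float)
    mat = np.abs(v[:, None] - v[None, :])
    return RDM(
        item_ids=list(item_ids),
        matrix=mat,
        source=f"text_feature({name})",
        degenerate=bool(np.ptp(v) == 0),
    )


def _check_aligned(rdms: Sequence[RDM]) -> None:
    ids = rdms[0].item_ids
    for r in rdms[1:]:
        if r.item_ids != ids:
            raise ValidationError(
                f"RDMs {rdms[0].source} and {r.source} have different item sets"
            )


def rdm_spearman(rdm_a: RDM, rdm_b: RDM) -> float:
    """Spearman rho over the strictly-upper triangles of two RDMs.

    NaN when either triangle is constant.
    """
    _check_aligned([rdm_a, rdm_b])
    ta, tb = rdm_a.triangle(), rdm_b.triangle()
    if np.ptp(ta) == 0 or np.ptp(tb) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(ta, tb)
    return float(rho)


# ---------------------------------------------------------------------------
# NNLS reweighting


def nnls_solve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||A w - b|| subject to w >= 0, via exact Gram reduction.

    The objective depends on A only through G = A'A and c = A'b, so the
    problem is reduced to an equivalent NNLS on the (k x k) eigenfactor
    of G before calling scipy's solver; exact, and much faster for long
    design matrices.  Returns (w, residual norm).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    G = A.T @ A
    c = A.T @ b
    evals, V = np.linalg.eigh(G)
    scale = float(evals.max(initial=0.0))
    if scale <= 0.0:
        raise ValidationError("degenerate NNLS fit: all candidates are zero")
    keep = evals > scale * 1e-12
    root = np.sqrt(evals[keep])
    F = root[:, None] * V[:, keep].T          # F'F = G (up to null space)
    g = (V[:, keep].T @ c) / root             # F'g = c  (c lies in range(G))
    w, _ = optimize.nnls(F, g)
    return w, float(np.linalg.norm(A @ w - b))


@dataclass
class RSAFit:
    """Result of cross-validated NNLS reweighting."""

    candidates: list[str]
    raw_weights: np.ndarray
    normalized_weights: np.ndarray
    cv_spearman: float
    train_spearman: float
    folds: int
    seed: int
    degenerate: bool = False
    fold_spearman: list[float] = field(default_factory=list)


def _heldout_mask(n: int, test_idx: np.ndarray) -> np.ndarray:
    """Upper-triangle mask of entries involving at least one held-out item."""
    held = np.zeros(n, dtype=bool)
    held[test_idx] = True
    iu, ju = np.triu_indices(n, k=1)
    return held[iu] | held[ju]


def _train_mask(n: int, test_idx: np.ndarray) -> np.ndarray:
    return ~_heldout_mask(n, test_idx)


def _triangle_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


def _finite_mean(values) -> float:
    finite = [v for v in values if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def nnls_reweight(
    candidates: Sequence[RDM],
    target: RDM,
    folds: int = 10,
    seed: int = 0,
) -> RSAFit:
    """Cross-validated non-negative reweighting of candidate RDMs.

    Items are split into seeded folds.  Per fold, NNLS fits the weights
    on the train x train upper-triangle entries; the recombined RDM is
    then correlated (Spearman) with the target on the held-out entries.
    Reported weights are the fold average, normalized to sum to 1;
    ``cv_spearman`` / ``train_spearman`` are the mean held-out / train
    correlations.  A fit whose weights are all zero in every fold is
    flagged degenerate.
    """
    if not candidates:
        raise ValidationError("at least one candidate RDM required")
    _check_aligned(list(candidates) + [target])
    n = target.n_items
    if folds < 2 or folds > n:
        raise ValidationError(f"folds must lie in 2..{n}")

    design = np.column_stack([c.triangle() for c in candidates])
    if not design.any():
        raise ValidationError("degenerate NNLS fit: all candidates are zero")
    tvec = target.triangle()

    weights, cv_rhos, train_rhos = [], [], []
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for _, test_idx in splitter.split(np.arange(n)):
        tr = _train_mask(n, test_idx)
        ho = ~tr
        w, _ = nnls_solve(design[tr], tvec[tr])
        weights.append(w)
        recombined = design @ w
        train_rhos.append(_triangle_spearman(recombined[tr], tvec[tr]))
        cv_rhos.append(_triangle_spearman(recombined[ho], tvec[ho]))

    raw = np.mean(weights, axis=0)
    total = raw.sum()
    degenerate = total <= 0
    normalized = raw / total if total > 0 else np.zeros_like(raw)
    return RSAFit(
        candidates=[c.source for c in candidates],
        raw_weights=raw,
        normalized_weights=normalized,
        cv_spearman=_finite_mean(cv_rhos),
        train_spearman=_finite_mean(train_rhos),
        folds=folds,
        seed=seed,
        degenerate=degenerate,
        fold_spearman=[float(r) for r in cv_rhos],
    )


def layerwise_reweight(
    layer_candidates: dict[int, Sequence[RDM]],
    target: RDM,
    folds: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[int, RSAFit]]:
    """One NNLS reweighting per layer, candidates restricted to that layer.

    Returns a long-format table (layer, candidate, normalized_weight,
    cv_spearman) plus the per-layer fits.  Used to trace which pooled
    representation dominates the explanatory recombination at each depth.
    """
    rows = []
    fits: dict[int, RSAFit] = {}
    for layer in sorted(layer_candidates):
        try:
            fit = nnls_reweight(
                list(layer_candidates[layer]), target, folds=folds, seed=seed
            )
        except ValidationError as err:
            raise ValidationError(f"layer {layer}: {err}") from err
        fits[layer] = fit
        for name, w in zip(fit.candidates, fit.normalized_weights):
            rows.append(
                {
                    "layer": layer,
                    "candidate": name,
                    "normalized_weight": float(w),
                    "cv_spearman": fit.cv_spearman,
                }
            )
    return pd.DataFrame(rows), fits
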