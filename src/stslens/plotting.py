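"""Optional matplotlib views of the analysis outputs.

All functions accept the long-format frames the pipeline writes and
return the created figure; nothing here is required by the analysis
itself.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless by default

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .rsa import RDM


def probe_curves(results: pd.DataFrame, rep_name: str, ax=None):
    """Layer-wise decoding curve (one line per model) for one representation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    sub = results[results["rep_name"] == rep_name]
    for model, grp in sub.groupby("model_name"):
        grp = grp.sort_values("layer")
        ax.plot(grp["layer"], grp["cv_pearson"], marker="o", label=model)
    ax.set_xlabel("layer")
    ax.set_ylabel("cross-validated Pearson r")
    ax.set_title(rep_name)
    ax.legend(fontsize=8)
    return ax.figure


def rdm_heatmap(rdm: RDM, scores=None, ax=None):
    """RDM heat map; when gold scores are given, items are sorted by
    score for display (computation elsewhere is order-invariant)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mat = rdm.matrix
    if scores is not None:
        order = np.argsort(np.asarray(scores), kind="mergesort")
        mat = mat[np.ix_(order, order)]
    im = ax.imshow(mat, cmap="viridis")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(rdm.source)
    return ax.figure


def layerwise_weight_surface(table: pd.DataFrame, model_name: str, ax=None):
    """Layer x representation surface of normalized NNLS weights."""
    sub = table[table["model_name"] == model_name]
    pivot = sub.pivot_table(
        index="candidate", columns="layer", values="normalized_weight"
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="magma")
    ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, fontsize=7)
    ax.set_xlabel("layer")
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"{model_name}: NNLS weight by layer")
    return ax.figure
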