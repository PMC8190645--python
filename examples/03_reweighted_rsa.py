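"""Reweighted and layer-wise RSA with a planted classification-token signal.

Plants a score encoding in the layer-3 [CLS] token of a small virtual
model, builds one RDM per (representation, layer) cell, and fits a
non-negative recombination of them to the ground-truth RDM (absolute
score differences) with cross-validated NNLS.  The layer-wise weight
table shows the planted cell absorbing the weight mass at its layer.
"""

from stslens import (
    CorpusConfig,
    ModelSpec,
    Planting,
    build_all,
    generate_activations,
    generate_corpus,
    ground_truth_rdm,
    layerwise_reweight,
    nnls_reweight,
)
from stslens.pipeline import _representation_rdms

corpus = generate_corpus(CorpusConfig(n_train=40, n_test=150), seed=5)
spec = ModelSpec("demo", n_layers=4, hidden_dim=32, layout="cls_first")
acts = generate_activations(corpus.test, spec, [Planting(3, "cls", 4.0)], seed=5)
table = build_all(acts, [1, 2, 3, 4])

ids = table.pair_ids
gold = {p.pair_id: p.score for p in corpus.test}
target = ground_truth_rdm(ids, [gold[i] for i in ids])
rep_rdms = _representation_rdms(table, ids)

fit = nnls_reweight(list(rep_rdms.values()), target, folds=10, seed=0)
print(f"All-layer reweighted RSA: held-out Spearman rho = {fit.cv_spearman:.3f}")
top = sorted(zip(fit.candidates, fit.normalized_weights), key=lambda t: -t[1])[:3]
for name, w in top:
    print(f"  weight {w:.3f}  {name}")

by_layer = {L: [rep_rdms[(rep, L)] for rep in table.rep_names] for L in (1, 2, 3, 4)}
weights, fits = layerwise_reweight(by_layer, target, folds=10, seed=0)
cls_rows = weights[weights.candidate.str.contains("cls,")]
print("\nNormalized weight on the [CLS] RDM per layer:")
print(cls_rows[["layer", "normalized_weight", "cv_spearman"]].to_string(index=False))
print("\nThe planted layer 3 concentrates the weight mass on [CLS].")
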