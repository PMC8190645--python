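"""Layer-wise linear decoding of planted activation signals.

Builds activations for a 12-layer virtual model with a linear score
signal planted at layer 6 in the mean-difference representation, then
probes every (layer, representation) cell with 10-fold cross-validated
linear regression.  The planted cell should top the ranking, and the
cross-validated Pearson r at layer 6 should be near-perfect.
"""

from stslens import (
    CorpusConfig,
    ModelSpec,
    Planting,
    build_all,
    decode_all,
    generate_activations,
    generate_corpus,
    rank_top,
    select_layers,
)

corpus = generate_corpus(CorpusConfig(n_train=60, n_test=300), seed=3)
spec = ModelSpec("virtual-12", n_layers=12, hidden_dim=64, layout="cls_first")
acts = generate_activations(
    corpus.test, spec, [Planting(layer=6, rep_name="sent_avg_difference",
                                 strength=2.0, noise_sd=0.5)], seed=3
)

table = build_all(acts, select_layers(12))
gold = {p.pair_id: p.score for p in corpus.test}
results = decode_all(table, gold, folds=10, seed=0)

print("Top 5 decoding cells (cross-validated Pearson r vs gold score):")
print(rank_top(results, 5)[["rep_name", "layer", "cv_pearson"]].to_string(index=False))

curve = results[results.rep_name == "sent_avg_difference"].sort_values("layer")
print("\nsent_avg_difference decoding curve across layers:")
print(curve[["layer", "cv_pearson"]].to_string(index=False))
print("\nThe planted layer 6 dominates; unplanted layers hover near zero.")
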