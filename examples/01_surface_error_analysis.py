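"""Surface-feature error analysis on a synthetic corpus.

Generates a corpus whose token overlap tracks the gold similarity
score, simulates a model that over-relies on that overlap, and prints
the per-label Spearman correlation between the model's squared-error
loss and the Jaccard distance of each pair.  A negative correlation at
low labels plus a positive one at high labels is the signature of the
planted overlap heuristic: the model over-predicts for overlapping but
dissimilar pairs and under-predicts for similar pairs with little
shared vocabulary.
"""

from stslens import BiasConfig, CorpusConfig, generate_corpus, generate_predictions
from stslens.data import count_tokens
from stslens.features import feature_table, loss_feature_correlations

corpus = generate_corpus(CorpusConfig(), seed=7)
preds = generate_predictions(
    corpus, BiasConfig(overlap_bias_strength=1.5, noise_sd=0.25), seed=7
)
rows = feature_table(corpus.test, count_tokens(corpus.train), preds.predictions)
corr = loss_feature_correlations(rows)

jac = corr[corr.feature == "jaccard_distance"]
print("Spearman rho between loss and Jaccard distance, per gold label:")
print(jac[["label", "rho", "p_bonferroni", "n"]].to_string(index=False))
print(
    "\nNegative rho at label 0.0 and positive rho at label 5.0 recover the"
    "\nplanted over-reliance on token overlap."
)
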