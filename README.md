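# stslens

Tools for dissecting how sentence-pair semantic-similarity models work:
surface-feature error analysis, layer-wise linear decoding of transformer
token representations, and reweighted representational similarity analysis
(RSA) — packaged with a synthetic-data generator that plants recoverable
structure, so the whole pipeline can be developed and validated without
access-restricted clinical text or GPU-trained checkpoints.

## The problem

Clinical semantic textual similarity (STS) systems score pairs of sentences
from health records on a 0–5 scale. Transformer ensembles do well on the
task, but *how* they do it matters: error analyses consistently show
over-reliance on shallow heuristics such as token overlap. `stslens`
implements three complementary analyses of a scored model:

1. **Surface-feature error analysis.** For each test pair the squared-error
   loss `(prediction − label)²` is correlated (Spearman ρ, Bonferroni
   corrected) with five surface features — total token count, train-corpus
   token frequency (stop words removed), unseen-token rate, across-sentence
   frequency difference, and the Jaccard distance
   `1 − |A ∩ B| / |A ∪ B|` between the pairs' token sets — overall and
   within each gold score level. An overlap-biased model leaves a
   characteristic signature: loss falls with Jaccard distance at low labels
   (over-prediction given overlap) and rises with it at high labels.

2. **Layer-wise linear probing.** Each layer's token vectors are pooled
   into ten fixed-size pair representations ([CLS] vector, mean/max pools
   of each sentence and their concatenations or absolute differences, the
   grand token mean, and two pooled cosine distances). A linear regression
   (minimum-norm least squares with intercept, 10-fold cross-validated)
   predicts the gold score from each (layer, representation) cell; the
   pooled out-of-fold Pearson r maps where in the network the similarity
   signal lives. 12-layer models are probed at every layer, 24-layer models
   at every other layer so depths compare by relative position.

3. **RSA with NNLS reweighting.** Representational dissimilarity matrices
   (RDMs) — cosine distance between pair representations, absolute
   difference for scalars and text features — are compared with the
   ground-truth RDM `|score_i − score_j|` by Spearman ρ over the upper
   triangle. Reweighted RSA fits a non-negative least-squares combination
   of candidate RDMs to the target under item-level 10-fold
   cross-validation, reporting fold-averaged weights normalized to sum
   to 1; a layer-wise variant restricts candidates to one layer at a time
   to trace which pooling dominates at each depth.

Because the real corpora (expert-scored clinical sentence pairs,
1642 train / 412 test) are access-restricted, the `synthetic` module
generates stand-ins at the same scale: Zipf-skewed vocabulary with a fixed
stop-word list, half-point score levels, token overlap coupled to the gold
score, biased model predictions, and layer-wise Gaussian activations into
which exact score encodings can be planted at any (layer, representation)
cell. Every analysis is validated as a recovery problem against those
plants.

## Worked example

`examples/02_layerwise_probing.py` plants a linear score signal at layer 6
of a 12-layer virtual model in the `sent_avg_difference` representation
and probes every cell:

```
Top 5 decoding cells (cross-validated Pearson r vs gold score):
             rep_name  layer  cv_pearson
  sent_avg_difference      6    0.987763
      avg_reps_concat      6    0.982734
sent_a_avg_max_concat      6    0.960739
  sent_max_difference      6    0.913331
      max_reps_concat      6    0.911999
```

The planted cell tops the ranking at r ≈ 0.99 (sibling representations at
the same layer inherit part of the signal because the plant shifts
sentence-A token vectors); unplanted layers decode near zero.
`examples/01_surface_error_analysis.py` shows the overlap-bias signature in
the loss/feature table (ρ = −0.34 at label 0.0, +0.41 at label 5.0 for the
Jaccard distance), and `examples/03_reweighted_rsa.py` shows layer-wise
NNLS reweighting concentrating 100% of its weight on a planted [CLS] RDM.

The same analyses run end-to-end from the shell:

```bash
stslens --seed 11 --outdir out/          # or: python -m stslens.cli
```

which writes TSV corpora and predictions, HDF5 activations and
representations, CSV feature/probing/RSA tables, and a `manifest.json`
with a SHA-256 checksum of every output. One root seed fixes every
artifact byte-for-byte.

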