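# metaphorspace

Dynamically contextual distributional semantics for graded metaphor
judgements.

Metaphor is contextual: *cut grass* is literal, *cut pollution* is not,
and the difference is not visible in any single static representation of
*cut*. `metaphorspace` models a verb–object dyad by building, on the
fly, a low-dimensional co-occurrence subspace specific to that pair of
words, and then reading the pair's semantics off the *statistical
geometry* of that subspace. It is aimed at computational
psycholinguists and NLP researchers who want an interpretable,
feature-level account of graded semantic judgements — metaphoricity,
meaningfulness, familiarity on 1–7 Likert scales, and a three-way
literal / conventional-metaphor / novel-metaphor classification.

## The model

**Base space.** From a plain-text corpus, a sparse word-by-context
matrix is built from co-occurrence counts in a symmetric ±2-word window
within sentences, over the V most frequent word types (rows; contexts
are all corpus types). Cells are weighted with a non-negative smoothed
PMI:

    PMI(w, c) = log2( f(w,c) · W / (f(w) · (f(c) + a)) + 1 )

with smoothing constant a = 10 000 damping rare contexts and the +1
forcing non-negativity (0 ⇔ the words never co-occur), so the space has
a meaningful origin, centre and periphery.

**Contextual subspaces.** For a dyad (w₁, w₂), k = 200 salient context
dimensions are selected by one of three techniques — **mean** (highest
arithmetic mean of the two PMI values), **geom** (highest geometric
mean √(PMI₁·PMI₂), requiring both to co-occur), or **indy** (the two
words' independently top-ranked contexts, interleaved, duplicates
skipped). Both word vectors V and N are projected into the subspace,
together with three generic vectors characterising the subspace itself:
the mean-vector M, maximum-vector X, and uniform central-vector C, plus
unit-normalised counterparts V′, N′, M′, X′, C′ on the unit sphere.

**Geometry → judgements.** Exactly 48 geometric features are extracted
per subspace: distances (‖V‖, ‖N‖, ‖VN‖, …), means and min/max ratios
of distance pairs to the generic vectors, directed fractions
(‖V‖/‖N‖, ‖C‖/‖M‖, …), angles at the origin and at generic-vector
vertices (∠VON, ∠VMN, …), and triangle areas (△VMN, …). These feed
leave-one-out cross-validated regressions: OLS for the graded ratings
(summarised by Pearson r of held-out predictions), one-vs-rest logistic
regression for the class (summarised by accuracy). Feature analysis
runs from single-feature |r| rankings to a collinearity-constrained
subset selected by a variance-inflation-factor walk
(admit a candidate iff 1/(1−R²) < 2, at most 5 features). A static-
embedding cosine baseline (word2vec text format) runs the same protocol
with a single predictor. Fisher r-to-z and permutation tests compare
models.

Because the original rated-dyad dataset and the full encyclopedic
corpus are not distributable, the package ships deterministic synthetic
generators (topic-structured corpora and feature-planted ratings) that
exercise every stage at desk scale; see `docs/methods.md` for what that
does and does not demonstrate.

## Worked example

Simulate a topic-structured corpus, build its PMI matrix, generate a
rated dyad table planted on the model's own features, and evaluate:

```sh
metaphorspace simulate corpus --seed 0 --out corpus.txt
metaphorspace build-matrix --corpus corpus.txt --vocab-size 200000 \
    --smoothing 10000 --out matrix
metaphorspace simulate dyads --seed 0 --matrix matrix \
    --n-dyads 60 --k 30 --out dyads.csv
metaphorspace features --matrix matrix --dyads dyads.csv \
    --technique indy --k 30 --out feats.csv
metaphorspace evaluate --features feats.csv --dyads dyads.csv \
    --mode vif --out eval.json
```

which prints/writes (seed 0):

```
3000 sentences -> corpus.txt
matrix: 205 rows x 205 contexts -> matrix
60 rated dyads -> dyads.csv
```

with held-out correlations in `eval.json` of r = 0.907 (metaphoricity),
0.852 (meaningfulness), 0.806 (familiarity) for the ≤5-feature
VIF-selected models. The same features in `--mode full` (all 48 in one
regression) give r = 0.588 / 0.490 / 0.229 and class accuracy 0.967 —
at n = 60 the full model overfits each leave-one-out fold, and the
non-collinear reduced model predicts markedly better, the same
qualitative gain the feature-selection stage is designed for. A single
projected subspace can also be inspected directly:

```sh
metaphorspace project --matrix matrix --verb t0w00 --noun t0w08 \
    --technique geom --k 30 --out sub.json
metaphorspace features --subspace sub.json --out f1.csv
```

giving, e.g., ‖V‖ = 2.358, ‖N‖ = 2.396, ‖VN‖ = 0.740, ∠VON = 0.312 rad,
‖V′N′‖ = 0.311 (= 2·sin(∠VON/2)), △VMN = 0.409: the two within-topic
words sit close together, far from the origin — the geometric signature
of a "literal" pairing in this model.

The full protocol (all techniques × targets, single-feature tables,
VIF models, significance tests, manifest) runs from one YAML config:

```sh
metaphorspace run --config run.yaml
```

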