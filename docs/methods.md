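# Methods

This note records the model as implemented, the parameter choices that
matter, the numerical conventions, and what the synthetic data can and
cannot show. It states nothing the test suite or the acceptance script
does not itself compute.

## Base space

Text is lowercased; punctuation is stripped except apostrophes and
hyphens; sentences are split at runs of `. ! ?` followed by whitespace
or end of text, *before* punctuation removal (so `den—cold!` tokenises
as `den`, `cold` in one sentence). These boundary and tokenisation
rules are a package convention — reasonable, documented, configurable
at the code level — not something the weighting scheme depends on.
Typographic apostrophes (`’`) are normalised to `'`.

The vocabulary is the `vocab_size` most frequent word types (default
200 000), ties broken lexicographically so builds are reproducible.
Co-occurrence is counted in a symmetric window of ±2 tokens within a
sentence; the window truncates at sentence edges; a word within the
window of another occurrence of itself *is* counted; context columns
are **all** corpus types, not just vocabulary rows (an optional
`min_context_count` filter exists for desk-scale hygiene, default off).

Weights are the non-negative smoothed PMI

PMI(w,c) = log₂( f(w,c)·W / (f(w)·(f(c)+a)) + 1 ),

with `W` the total token count of vocabulary words, recomputed from the
same sentence stream as the counts so the table's internal invariants
(Σ_c f(w,c) ≤ 2·window·f(w), W = Σ f(w)) hold by construction. The
smoothing constant `a` (default 10 000) is chosen to be of the order of
the mean context frequency in a large corpus: it halves the typical
frequency ratio, severely punishing extremely rare contexts while
barely touching common ones. The +1 inside the log guarantees
non-negativity, with 0 reserved for "never co-occurs"; this is what
gives subspaces a meaningful origin, centre and periphery. Stored cells
are therefore strictly positive and sparsity is preserved exactly.
Matrices persist as MatrixMarket coordinate files (written at 17
significant digits, so float64 round-trips are bit-exact) plus row and
column label TSVs.

## Subspace projection

For a dyad (w₁, w₂) and size k (default 200):

* **mean** — score every context with at least one non-zero value by
  (PMI₁+PMI₂)/2 and take the top k;
* **geom** — score by √(PMI₁·PMI₂), defined only where both values are
  positive (zero annihilates the product; the square-root form is the
  one consistent with the worked combination (9,1) → 3);
* **indy** — interleave the two words' own PMI rankings, verb first,
  skipping dimensions already selected; if one list is exhausted the
  remainder comes from the other.

All top-k selections break score ties lexicographically on the context
type. On corpora too small to supply k candidates, geom falls back to
arithmetic-mean ranking for the remaining slots with a warning; mean
and indy return all available dimensions with a warning in permissive
mode and raise in strict mode. Coordinates in the subspace are simply
the base-space PMI values.

Generic vectors: M_j is the mean of the *non-zero* vocabulary values in
column j (0 for an empty column), X_j the column maximum over the whole
vocabulary, C the uniform vector at the mean of M's elements. X
element-wise dominates V, N and M by construction. Normalised
counterparts divide by the Euclidean norm; the zero vector is an error
in strict mode and maps to itself in permissive mode, with downstream
features that need its direction flagged undefined (NaN).

## The 48 geometric features

Seven distances (‖V‖, ‖N‖, ‖VN‖, ‖M‖, ‖X‖, ‖C‖, ‖V′N′‖), six means of
distance pairs to generic vectors (full and normalised), six min/max
ratios of the same pairs, thirteen directed fractions, ten angles and
six triangle areas — 48 named values in a fixed canonical order used by
every serialisation.

Conventions: angles are radians in [0, π], computed as the arccos of a
cosine clamped to [−1, 1]; reports may convert to degrees but the
stored value is radians. Ratios are oriented min/max ("the lower over
the higher"): both distances zero → 1, exactly one zero → 0, so ratios
live in [0, 1]. Directed fractions keep their stated orientation; a
zero denominator is NaN in permissive mode, an error in strict mode.
Triangle areas use the Gram form ½√(‖a‖²‖b‖² − (a·b)²), valid in any
ambient dimension, with the radicand clamped at 0 so collinear triples
give exactly 0 (the suite cross-checks against Heron's formula and the
law of cosines).

Two structural notes. Exchanging V and N leaves the genuinely
symmetric features unchanged and maps the directed fractions to their
reciprocals, but ‖V‖ and ‖N‖ trade places and the V-anchored areas
(△VXM, △VCM and normalised analogues) have no N-anchored counterparts
in the feature list — the set is deliberately asymmetric in V. And on
the unit sphere ‖V′N′‖ = 2·sin(∠VON/2) exactly, so the normalised
separation and the origin angle carry the same information
monotonically; both are kept because the collinearity-control stage
exists precisely to adjudicate such redundancies.

## Evaluation protocol

Features are z-scored (sample SD) once over the whole dataset before
cross-validation; constant columns become zeros with a warning. This
whole-dataset standardization implies a mild train/test leakage that is
part of the protocol being modelled; a leakage-free variant that
re-standardizes inside each training fold is available via
`fold_standardize=True` on both cross-validation functions.

* **Graded ratings** — leave-one-out OLS (intercept included);
  rank-deficient designs take the minimum-norm pseudoinverse solution
  with a warning; the summary is the Pearson r between the n held-out
  predictions and the true ratings.
* **Class** — leave-one-out one-vs-rest logistic regression: one
  binary maximum-likelihood model per class (effectively unregularised,
  C = 10⁶; on non-convergence, e.g. complete separation, a fixed L2
  fallback at C = 1 with a warning), predicted class = highest
  probability, ties broken lexicographically. Successive folds
  warm-start from the previous optimum, which changes nothing about the
  objective but makes the 3n fits fast.
* **Single features** — per-feature Pearson r against each rating,
  ranked by |r| descending, ties lexicographic; zero-variance features
  get r = 0 with a warning.
* **VIF selection** — seed with the top-|r| feature, walk down the
  ranking, regress each candidate on the current selection and admit it
  iff 1/(1−R²) < fac (default 2), stopping at 5 features. The class
  model in the reduced mode reuses the metaphoricity-selected set,
  metaphoricity being the class-defining gradient.
* **Significance** — Fisher r-to-z for correlation differences
  (independent-samples form; the correlations compared in practice
  share items, so these p-values are conservative approximations, which
  we note rather than correct) and seeded permutation tests for
  classifier differences: label-shuffling null for one prediction set,
  paired sign-flips for two, p = (1 + #{perm ≥ obs}) / (n_perm + 1),
  with exact enumeration available for small n.

A known artefact worth recording: with a completely uninformative
(constant) feature, LOO one-vs-rest prediction is *anti*-correlated
with the truth — the held-out item's own class always has one fewer
positive example in the training fold, so the argmax systematically
avoids it and accuracy is 0, not 1/3. The meaningful chance reference
is the single-class predictor, whose accuracy on a balanced three-way
design is exactly 1/3 (76/228).

## Baseline

A static embedding table in word2vec text format supplies one number
per dyad — the cosine of the two word vectors. That number is
correlated directly with each rating and fed, as the sole feature,
through the identical LOO one-vs-rest protocol. Dyads with a missing
word are dropped with a logged count (strict mode errors). The baseline
is a strict p = 1 special case of the regression module and is tested
as such.

## Synthetic data: what it shows

`micro_corpus()` is a frozen 12-sentence corpus whose counts are
hand-tabulated in the suite. `generate_corpus` samples a
topic-structured corpus: topics with private word stocks plus a
configurable number of bridge words per topic pair, so within-topic
pairs share many co-occurrence dimensions and cross-topic pairs share
only bridges (none, when `bridge_words=0` — which empties the geom
candidate set across topics). Defaults: 6 topics × 30 words, 4 bridges
per pair, 3 000 sentences of 5–12 tokens. Sampling is uniform within a
topic pool via a seeded PCG64 generator, so output is reproducible
across platforms.

`generate_dyad_dataset` plants a latent metaphoricity signal as a
linear combination of the model's own geometric features (defaults:
∠VON, μ(‖VX‖,‖NX‖), ‖VC‖/‖NC‖), standardizes it, and maps it onto the
1–7 scale with Gaussian noise (SD 0.5). Rating centres and slopes
(metaphoricity 3.91 + 1.05·z, meaningfulness 5.08 − 0.87·z, familiarity
2.99 − 0.78·z) emulate the class-mean structure of published normative
ratings for this kind of stimulus set, and give metaphoricity its
characteristic negative correlations with the other two judgements.
Classes are latent-score terciles — balanced by construction (76/76/76
at the default n = 228).

This construction is **circular by design**: ratings are generated from
the very features the regressions consume. Passing tests therefore
demonstrate that the machinery — projection, feature extraction,
cross-validation, ranking, VIF selection — recovers planted structure
correctly; they say nothing about whether real human judgements are
predictable from these features, which requires the original corpus
and rating data.

## Problem sizes

The full-scale configuration (200 000-word vocabulary, ~9 M context
types, k = 200, n = 228 dyads) is the package default where it is a
free parameter. The suite and the end-to-end determinism check run a
desk-scale configuration chosen as a package convention: a 4-topic ×
16-word corpus of 800 sentences, 90 dyads, k = 25 — small enough that
every stage, including two full report-bundle builds for the
byte-identity check, completes in well under a minute, while still
exercising every code path (including the geom fallback, which any
corpus with only a few hundred context types will trigger at large k).
For the same reason the demonstration configs in the README use k in
the tens: a synthetic corpus simply does not have 200 informative
dimensions per dyad.

## Known limitations

* Sentence splitting is rule-based (`.!?` + whitespace); abbreviations
  produce spurious boundaries.
* The indy technique is order-dependent when duplicate-skips occur, so
  verb/noun swaps can change the selected dimension multiset; mean and
  geom are swap-invariant as sets.
* Uniform within-topic sampling gives the synthetic corpus no Zipfian
  tail, so smoothing behaves more gently than on natural text.
* The Fisher tests treat compared correlations as independent samples;
  with overlapping items they are conservative.
* No composition operators between V and N are provided: the two words
  are analysed as separate points of one subspace, by design.
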