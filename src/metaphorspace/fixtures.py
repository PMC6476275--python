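"""Deterministic synthetic data for desk-scale experiments.

Three generators stand in for resources the full pipeline was designed
around but which cannot ship with the package: a large encyclopedic
corpus and a table of human-rated verb-object dyads.

* :func:`micro_corpus` — a frozen dozen-sentence corpus whose
  co-occurrence counts are small enough to tabulate by hand.
* :func:`generate_corpus` — a topic-structured corpus: each topic has
  its own word stock plus "bridge" words shared with every other
  topic, so planted word pairs have controllably overlapping
  co-occurrence profiles (within-topic pairs share many dimensions,
  cross-topic pairs only the bridges).
* :func:`generate_dyad_dataset` — graded ratings generated as a known
  linear combination of the model's own geometric features plus
  Gaussian noise. This is circular **by design**: it validates the
  recovery machinery (regression, ranking, VIF selection), not any
  empirical claim about human metaphor judgements. Rating centres and
  slopes emulate published normative shapes: a 1-7 Likert scale,
  three balanced classes, and metaphoricity negatively correlated
  with both meaningfulness and familiarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regress import FeatureMatrix, standardize_features

__all__ = [
    "MICRO_CORPUS_TEXT",
    "SyntheticCorpusSpec",
    "SyntheticRatingSpec",
    "micro_corpus",
    "generate_corpus",
    "planted_dyads",
    "generate_dyad_dataset",
]

MICRO_CORPUS_TEXT = (
    "the cat sat on the mat. "
    "the dog sat on the rug. "
    "a cat saw the dog. "
    "the dog saw a bird. "
    "a bird sang on the mat. "
    "the cat chased a bird. "
    "dogs bark. "
    "cats purr. "
    "the mat was red. "
    "the rug was blue. "
    "a dog and a cat played. "
    "the cat slept on the rug."
)


def micro_corpus() -> str:
    """The frozen micro-corpus (identical text on every call)."""
    return MICRO_CORPUS_TEXT


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Topic-structured corpus parameters.

    ``bridge_words`` is the number of word types shared by each
    unordered topic pair (0 = topics are lexically disjoint).
    """

    n_topics: int = 6
    words_per_topic: int = 30
    bridge_words: int = 4
    n_sentences: int = 3000
    sentence_length: tuple[int, int] = (5, 12)
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1 or self.words_per_topic < 1 or self.n_sentences < 1:
            raise ValidationError("topic, word and sentence counts must be >= 1")
        if self.bridge_words < 0:
            raise ValidationError("bridge_words must be >= 0")
        lo, hi = self.sentence_length
        if lo < 1 or hi < lo:
            raise ValidationError("sentence_length must satisfy 1 <= lo <= hi")


def _topic_words(spec: SyntheticCorpusSpec, t: int) -> list[str]:
    return [f"t{t}w{i:02d}" for i in range(spec.words_per_topic)]


def _bridge_words(spec: SyntheticCorpusSpec, i: int, j: int) -> list[str]:
    i, j = min(i, j), max(i, j)
    return [f"b{i}_{j}w{m:02d}" for m in range(spec.bridge_words)]


def _topic_pool(spec: SyntheticCorpusSpec, t: int) -> list[str]:
    pool = _topic_words(spec, t)
    for u in range(spec.n_topics):
        if u != t:
            pool += _bridge_words(spec, t, u)
    return pool


def generate_corpus(spec: SyntheticCorpusSpec) -> list[list[str]]:
    """Sample a clean sentence stream from the topic structure.

    Each sentence draws a topic, a length, then tokens uniformly from
    the topic's pool (own words + bridges to every other topic). Fully
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    pools = [_topic_pool(spec, t) for t in range(spec.n_topics)]
    lo, hi = spec.sentence_length
    sentences = []
    for _ in range(spec.n_sentences):
        t = int(rng.integers(spec.n_topics))
        length = int(rng.integers(lo, hi + 1))
        pool = pools[t]
        picks = rng.integers(0, len(pool), size=length)
        sentences.append([pool[p] for p in picks])
    return sentences


def planted_dyads(
    spec: SyntheticCorpusSpec, n_dyads: int
) -> list[tuple[str, str]]:
    """Deterministic verb-noun pairs over the synthetic vocabulary.

    "Verbs" are the first half of each topic's word stock, "nouns" the
    second half. Within-topic pairs (heavily overlapping co-occurrence
    profiles) alternate with adjacent-cross-topic pairs (overlap only
    through bridges), giving the planted feature matrix real variance.
    """
    half = spec.words_per_topic // 2
    if half < 1:
        raise ValidationError("words_per_topic must be >= 2 to plant dyads")
    within, cross = [], []
    for t in range(spec.n_topics):
        words = _topic_words(spec, t)
        nxt = _topic_words(spec, (t + 1) % spec.n_topics)
        for i in range(half):
            for j in range(half):
                within.append((words[i], words[half + j]))
                cross.append((words[i], nxt[half + j]))
    dyads: list[tuple[str, str]] = []
    seen = set()
    for w, x in (p for pair in zip(within, cross) for p in pair):
        if (w, x) not in seen:
            dyads.append((w, x))
            seen.add((w, x))
        if len(dyads) == n_dyads:
            return dyads
    raise ValidationError(
        f"cannot plant {n_dyads} distinct dyads from this corpus spec"
    )


@dataclass(frozen=True)
class SyntheticRatingSpec:
    """How graded ratings are synthesised from geometric features.

    ``coefficients`` defines the latent metaphoricity signal as a
    linear combination of (internally standardized) features; the
    latent score is itself standardized before being mapped onto the
    1-7 scale. Centres/slopes default to values emulating published
    normative shapes: mean metaphoricity ~3.9 rising with the latent
    score, meaningfulness ~5.1 and familiarity ~3.0 both falling.
    Classes are assigned by latent-score terciles (``class_quantiles``),
    balanced by construction.
    """

    coefficients: tuple[tuple[str, float], ...] = (
        ("angle_VON", 1.0),
        ("mean_VX_NX", 0.6),
        ("frac_VC_NC", 0.4),
    )
    noise_sd: float = 0.5
    clip_range: tuple[float, float] = (1.0, 7.0)
    class_quantiles: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    centers: tuple[float, float, float] = (3.91, 5.08, 2.99)
    slopes: tuple[float, float, float] = (1.05, -0.87, -0.78)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.clip_range
        if not lo < hi:
            raise ValidationError("clip_range must be increasing")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        q1, q2 = self.class_quantiles
        if not 0.0 < q1 < q2 < 1.0:
            raise ValidationError("class_quantiles must be strictly inside (0, 1)")


def generate_dyad_dataset(
    spec: SyntheticRatingSpec,
    features: FeatureMatrix,
    dyads: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Synthesize a rated-dyad table from a feature matrix.

    Metaphoricity follows the planted linear signal plus Gaussian
    noise, clipped to the rating scale; meaningfulness and familiarity
    follow the same latent score with negative slopes (and independent
    noise), reproducing the negative correlations between metaphoricity
    and the other two judgements. Classes come from latent terciles.
    """
    if not isinstance(features, FeatureMatrix):
        features = FeatureMatrix(pd.DataFrame(features))
    n = len(features)
    if n < 3:
        raise ValidationError("need at least 3 dyads for three classes")
    missing = [f for f, _ in spec.coefficients if f not in features.data.columns]
    if missing:
        raise ValidationError(f"coefficient features absent from matrix: {missing}")

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # constant columns are fine here
        Z = standardize_features(features).data
    latent = np.zeros(n)
    for name, coef in spec.coefficients:
        latent += coef * Z[name].to_numpy(dtype=np.float64)
    sd = latent.std(ddof=1)
    if sd > 0:
        latent = (latent - latent.mean()) / sd

    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.clip_range
    ratings = {}
    for name, center, slope in zip(
        ("metaphoricity", "meaningfulness", "familiarity"),
        spec.centers,
        spec.slopes,
    ):
        noise = rng.standard_normal(n) * spec.noise_sd
        ratings[name] = np.clip(center + slope * latent + noise, lo, hi)

    order = np.argsort(latent, kind="stable")
    q1, q2 = spec.class_quantiles
    c1, c2 = int(round(n * q1)), int(round(n * q2))
    classes = np.empty(n, dtype=object)
    classes[order[:c1]] = "literal"
    classes[order[c1:c2]] = "conventional"
    classes[order[c2:]] = "novel"
    if len(set(classes)) < 3:
        raise ValidationError("class thresholds left a class empty")

    if dyads is None:
        if isinstance(features.data.index, pd.MultiIndex):
            dyads = list(features.data.index)
        else:
            dyads = [(f"verb{i:03d}", f"noun{i:03d}") for i in range(n)]
    if len(dyads) != n:
        raise ValidationError("dyad list length does not match feature rows")

    return pd.DataFrame(
        {
            "verb": [v for v, _ in dyads],
            "noun": [x for _, x in dyads],
            "class": classes,
            "metaphoricity": ratings["metaphoricity"],
            "meaningfulness": ratings["meaningfulness"],
            "familiarity": ratings["familiarity"],
        }
    )
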