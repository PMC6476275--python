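"""Static-embedding baseline.

A single static vector space (e.g. word2vec trained externally) admits
exactly one comparison between the two words of a dyad: cosine
similarity. That one number is correlated with each graded judgement
and fed, as the sole feature, through the same leave-one-out
one-vs-rest logistic protocol as the subspace geometry — a deliberately
minimal point of comparison for the contextual model.

Only the standard word2vec *text* format is supported: a header line
``<count> <dim>`` followed by ``word v1 ... vd`` lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmbeddingFormatError, MetaphorspaceError
from .regress import (
    CVResult,
    FeatureMatrix,
    RATING_COLUMNS,
    _pearson,
    loo_logistic_ovr_cv,
    standardize_features,
)

__all__ = [
    "EmbeddingTable",
    "load_embeddings",
    "save_embeddings",
    "dyad_cosines",
    "baseline_evaluate",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingTable:
    vectors: dict[str, np.ndarray]
    dim: int

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def load_embeddings(path: str | Path) -> EmbeddingTable:
    """Read word2vec text format, validating the declared count/dim."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise EmbeddingFormatError(
                "line 1: header must be '<count> <dim>', got "
                f"{' '.join(header)!r}"
            )
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as e:
            raise EmbeddingFormatError(f"line 1: non-integer header: {e}") from e
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise EmbeddingFormatError(
                    f"line {lineno}: expected {dim} values for "
                    f"{parts[0]!r}, got {len(parts) - 1}"
                )
            word = parts[0]
            if word in vectors:
                raise EmbeddingFormatError(f"line {lineno}: duplicate word {word!r}")
            try:
                vectors[word] = np.array(parts[1:], dtype=np.float64)
            except ValueError as e:
                raise EmbeddingFormatError(f"line {lineno}: bad float: {e}") from e
    if len(vectors) != count:
        raise EmbeddingFormatError(
            f"header declares {count} words but file holds {len(vectors)}"
        )
    return EmbeddingTable(vectors, dim)


def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def cosine(v: np.ndarray, w: np.ndarray) -> float:
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        return float("nan")
    return float(np.dot(v, w) / (nv * nw))


def dyad_cosines(
    emb: EmbeddingTable, dyads: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Append a ``cosine`` column to the dyad table.

    Dyads with an out-of-vocabulary word are dropped with a logged
    count (or raise in strict mode).
    """
    keep, cos = [], []
    n_dropped = 0
    for i, row in dyads.iterrows():
        v, n = row["verb"], row["noun"]
        if v not in emb or n not in emb:
            if strict:
                raise MetaphorspaceError(f"embedding missing for dyad ({v!r}, {n!r})")
            n_dropped += 1
            continue
        keep.append(i)
        cos.append(cosine(emb.vectors[v], emb.vectors[n]))
    if n_dropped:
        logger.warning("dropped %d dyads with out-of-vocabulary words", n_dropped)
    out = dyads.loc[keep].copy()
    out["cosine"] = cos
    return out


def baseline_evaluate(with_cosine: pd.DataFrame) -> dict[str, CVResult]:
    """Cosine-only evaluation: Pearson r against each rating, plus
    leave-one-out one-vs-rest accuracy with cosine as the sole feature."""
    cos = with_cosine["cosine"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(cos)):
        raise MetaphorspaceError("non-finite cosine values in baseline input")
    results: dict[str, CVResult] = {}
    for rating in RATING_COLUMNS:
        y = with_cosine[rating].to_numpy(dtype=np.float64)
        results[rating] = CVResult(cos.copy(), _pearson(cos, y), "r", rating, "w2v")
    F = standardize_features(FeatureMatrix(with_cosine[["cosine"]].copy()))
    res = loo_logistic_ovr_cv(F, with_cosine["class"].to_numpy(), technique="w2v")
    results["class"] = res
    return results
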