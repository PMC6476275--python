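"""Dyad-contextual subspace projection.

Given a verb-object dyad, a low-dimensional subspace is carved out of
the base PMI space by selecting the k context dimensions most salient
to the pair, under one of three techniques:

``mean``
    highest arithmetic mean of the two words' PMI values,
    M(c) = (PMI(w1,c) + PMI(w2,c)) / 2;
``geom``
    highest geometric mean, G(c) = sqrt(PMI(w1,c) * PMI(w2,c)),
    which is non-zero only where *both* words co-occur with c;
``indy``
    the two words' independently top-ranked contexts, interleaved
    (verb first), skipping duplicates, until k dimensions are collected.

Both word vectors are projected into the subspace (coordinates are just
the base-space PMI values), together with three *generic* vectors that
characterise the subspace itself: the mean-vector M (per-dimension mean
of the non-zero vocabulary values), the maximum-vector X (per-dimension
max), and the central-vector C (uniform, at the mean of M's elements).
Unit-normalised counterparts of all five vectors live on the unit
sphere; the distance between normalised vectors increases monotonically
with the angle at the origin.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import PMIMatrix
from .errors import DegenerateSubspaceError, DegenerateVectorError

__all__ = [
    "DyadQuery",
    "DimensionScore",
    "Subspace",
    "score_dimensions",
    "select_dimensions",
    "project_word",
    "generic_vectors",
    "normalize",
]

logger = logging.getLogger(__name__)

TECHNIQUES = ("indy", "mean", "geom")


@dataclass(frozen=True)
class DyadQuery:
    """A verb-object dyad plus the projection technique and size k."""

    word1: str  # verb
    word2: str  # object noun
    technique: str = "indy"
    k: int = 200

    def __post_init__(self):
        if self.technique not in TECHNIQUES:
            raise ValueError(f"technique must be one of {TECHNIQUES}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class DimensionScore:
    context: str
    score: float


def _dense_row(pmi: PMIMatrix, word: str) -> np.ndarray:
    return np.asarray(pmi.row(word).todense()).ravel()


def score_dimensions(
    pmi: PMIMatrix, w1: str, w2: str, technique: str
) -> list[DimensionScore]:
    """Combined salience score of every candidate context dimension.

    ``mean`` scores every context where at least one word has non-zero
    PMI; ``geom`` only those where both do (zero annihilates a product).
    """
    if technique not in ("mean", "geom"):
        raise ValueError("score_dimensions applies to the mean and geom techniques")
    r1, r2 = _dense_row(pmi, w1), _dense_row(pmi, w2)
    if technique == "mean":
        mask = (r1 > 0) | (r2 > 0)
        scores = (r1 + r2) / 2.0
    else:
        mask = (r1 > 0) & (r2 > 0)
        scores = np.sqrt(r1 * r2)
    idx = np.flatnonzero(mask)
    return [DimensionScore(pmi.col_words[j], float(scores[j])) for j in idx]


def _ranked(scored: list[DimensionScore]) -> list[DimensionScore]:
    """Score descending, context lexicographic ascending on ties."""
    return sorted(scored, key=lambda d: (-d.score, d.context))


def select_dimensions(
    pmi: PMIMatrix, q: DyadQuery, strict: bool = False
) -> list[str]:
    """Select the ordered k context dimensions for a dyad query.

    On corpora too small to supply k candidates: geom falls back to
    arithmetic-mean ranking for the remaining slots (with a warning);
    mean/indy return all available dimensions (fewer than k) in
    permissive mode, or raise in strict mode.
    """
    if q.technique == "indy":
        dims = _select_indy(pmi, q)
    elif q.technique == "mean":
        dims = [d.context for d in _ranked(score_dimensions(pmi, q.word1, q.word2, "mean"))[: q.k]]
    else:
        geom_ranked = _ranked(score_dimensions(pmi, q.word1, q.word2, "geom"))
        if not geom_ranked:
            raise DegenerateSubspaceError(
                f"no context dimension has positive PMI for both "
                f"{q.word1!r} and {q.word2!r}"
            )
        dims = [d.context for d in geom_ranked[: q.k]]
        if len(dims) < q.k:
            warnings.warn(
                f"geom found only {len(dims)} positive-product dimensions for "
                f"({q.word1!r}, {q.word2!r}); filling from arithmetic-mean ranking",
                stacklevel=2,
            )
            chosen = set(dims)
            for d in _ranked(score_dimensions(pmi, q.word1, q.word2, "mean")):
                if len(dims) >= q.k:
                    break
                if d.context not in chosen:
                    dims.append(d.context)
                    chosen.add(d.context)

    if len(dims) < q.k:
        msg = (
            f"only {len(dims)} candidate dimensions available for "
            f"({q.word1!r}, {q.word2!r}) with technique {q.technique!r} (k={q.k})"
        )
        if strict:
            raise DegenerateSubspaceError(msg)
        warnings.warn(msg, stacklevel=2)
    return dims


def _word_ranking(pmi: PMIMatrix, word: str) -> list[str]:
    row = pmi.row(word).tocoo()
    pairs = sorted(
        zip(-row.data, (pmi.col_words[j] for j in row.col))
    )
    return [c for _, c in pairs]


def _select_indy(pmi: PMIMatrix, q: DyadQuery) -> list[str]:
    """Strict alternation starting with the verb; duplicates skipped;
    when one word's candidates run out the rest come from the other."""
    rankings = [_word_ranking(pmi, q.word1), _word_ranking(pmi, q.word2)]
    pos = [0, 0]
    dims: list[str] = []
    chosen: set[str] = set()
    turn = 0
    while len(dims) < q.k:
        ranking = rankings[turn]
        i = pos[turn]
        while i < len(ranking) and ranking[i] in chosen:
            i += 1
        if i < len(ranking):
            dims.append(ranking[i])
            chosen.add(ranking[i])
            pos[turn] = i + 1
        else:
            other = rankings[1 - turn]
            j = pos[1 - turn]
            while len(dims) < q.k and j < len(other):
                if other[j] not in chosen:
                    dims.append(other[j])
                    chosen.add(other[j])
                j += 1
            break
        turn = 1 - turn
    return dims


def project_word(pmi: PMIMatrix, dims: list[str], word: str) -> np.ndarray:
    """Coordinates of ``word`` on the selected dimensions (base PMI values)."""
    row = _dense_row(pmi, word)
    cols = [pmi._col_index.get(c) for c in dims]
    return np.array([row[j] if j is not None else 0.0 for j in cols])


def generic_vectors(
    pmi: PMIMatrix, dims: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-, maximum- and central-vector of a subspace.

    M_j averages the non-zero PMI values in column j over the whole
    vocabulary (0 if the column is empty); X_j is the column maximum;
    C is uniform with every element equal to the mean of M's elements.
    """
    if not dims:
        raise ValueError("dims must be non-empty")
    cols = [pmi._col_index.get(c) for c in dims]
    csc = pmi.matrix.tocsc()
    k = len(dims)
    M = np.zeros(k)
    X = np.zeros(k)
    for out_j, j in enumerate(cols):
        if j is None:
            continue
        data = csc.data[csc.indptr[j] : csc.indptr[j + 1]]
        if data.size:
            M[out_j] = data.mean()
            X[out_j] = data.max()
    C = np.full(k, M.mean())
    return M, X, C


def normalize(v: np.ndarray, strict: bool = False) -> np.ndarray:
    """Rescale to unit Euclidean norm; the zero vector maps to itself
    in permissive mode and raises :class:`DegenerateVectorError` in
    strict mode."""
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0.0:
        if strict:
            raise DegenerateVectorError("cannot normalize the zero vector")
        return v.copy()
    return v / n


@dataclass
class Subspace:
    """A projected dyad subspace: dimensions, word vectors V (verb) and
    N (noun), generic vectors M/X/C, and unit-normalised counterparts.

    The origin O is the zero vector by convention.
    """

    dims: list[str]
    V: np.ndarray
    N: np.ndarray
    M: np.ndarray
    X: np.ndarray
    C: np.ndarray
    word1: str = ""
    word2: str = ""
    technique: str = ""
    Vn: np.ndarray = field(init=False)
    Nn: np.ndarray = field(init=False)
    Mn: np.ndarray = field(init=False)
    Xn: np.ndarray = field(init=False)
    Cn: np.ndarray = field(init=False)

    def __post_init__(self):
        for name in ("V", "N", "M", "X", "C"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        self.Vn = normalize(self.V)
        self.Nn = normalize(self.N)
        self.Mn = normalize(self.M)
        self.Xn = normalize(self.X)
        self.Cn = normalize(self.C)

    @classmethod
    def project(
        cls, pmi: PMIMatrix, q: DyadQuery, strict: bool = False
    ) -> "Subspace":
        dims = select_dimensions(pmi, q, strict=strict)
        V = project_word(pmi, dims, q.word1)
        N = project_word(pmi, dims, q.word2)
        M, X, C = generic_vectors(pmi, dims)
        return cls(dims, V, N, M, X, C, q.word1, q.word2, q.technique)

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "word1": self.word1,
            "word2": self.word2,
            "technique": self.technique,
            "dims": list(self.dims),
        }
        for name in ("V", "N", "M", "X", "C", "Vn", "Nn", "Mn", "Xn", "Cn"):
            d[name] = getattr(self, name).tolist()
        return d

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Subspace":
        return cls(
            dims=list(d["dims"]),
            V=np.array(d["V"]),
            N=np.array(d["N"]),
            M=np.array(d["M"]),
            X=np.array(d["X"]),
            C=np.array(d["C"]),
            word1=d.get("word1", ""),
            word2=d.get("word2", ""),
            technique=d.get("technique", ""),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "Subspace":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
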