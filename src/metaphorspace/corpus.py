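"""Corpus cleaning, vocabulary construction, and smoothed PMI weighting.

The base space is a sparse word-by-context matrix built from windowed
co-occurrence counts within sentences. Cell weights use a non-negative
variant of pointwise mutual information,

    PMI(w, c) = log2( f(w,c) * W / (f(w) * (f(c) + a)) + 1 )

where ``f(w,c)`` is the co-occurrence count, ``f(w)`` and ``f(c)`` are
marginal token frequencies, ``W`` is the total count of vocabulary-word
tokens, and ``a`` is a smoothing constant (default 10 000) that damps
the otherwise exaggerated weight of very rare context words. The ``+1``
inside the logarithm makes every weight non-negative, with 0 reserved
for pairs that never co-occur — a property the downstream subspace
geometry relies on (origin, centre and periphery are meaningful).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .errors import (
    CorpusDecodingError,
    EmptyCorpusError,
    InvalidTableError,
    OutOfVocabularyError,
)

__all__ = [
    "PMIConfig",
    "Vocabulary",
    "CooccurrenceTable",
    "PMIMatrix",
    "clean_corpus",
    "build_vocabulary",
    "count_cooccurrences",
    "compute_pmi",
]

# Sentence boundaries are detected before punctuation stripping: a run of
# terminal punctuation followed by whitespace or end of text.
_SENTENCE_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)")

# Every character that is not a letter, digit, apostrophe or hyphen is
# replaced by a space (so "den—cold" splits into two tokens). Underscore
# is matched by \w and must be removed explicitly.
_NON_TOKEN = re.compile(r"[^\w'\-]|_", re.UNICODE)


def clean_corpus(raw: str | bytes | Iterable[str]) -> Iterator[list[str]]:
    """Clean raw text and yield sentences as lists of lowercase tokens.

    Punctuation is removed (replaced by spaces) except apostrophes and
    hyphens; text is lowercased; sentences are split at terminal
    ``. ! ?`` runs. When ``raw`` is an iterable of strings (e.g. a file
    object with one document per line), sentences never cross chunks.

    Raises
    ------
    CorpusDecodingError
        If ``raw`` is ``bytes`` that cannot be decoded as UTF-8.
    """
    if isinstance(raw, bytes):
        try:
            chunks: Iterable[str] = [raw.decode("utf-8")]
        except UnicodeDecodeError as e:
            raise CorpusDecodingError(e.start, e.reason) from e
    elif isinstance(raw, str):
        chunks = [raw]
    else:
        chunks = raw

    for chunk in chunks:
        text = chunk.lower().replace("’", "'")
        for part in _SENTENCE_BOUNDARY.split(text):
            tokens = _NON_TOKEN.sub(" ", part).split()
            if tokens:
                yield tokens


@dataclass(frozen=True)
class PMIConfig:
    """Parameters of the PMI weighting. ``log_base`` is fixed at 2."""

    smoothing_a: float = 10_000.0
    log_base: int = 2

    def __post_init__(self):
        if self.smoothing_a < 0:
            raise ValueError("smoothing_a must be non-negative")
        if self.log_base != 2:
            raise ValueError("log_base is fixed at 2")


@dataclass
class Vocabulary:
    """The ``size_limit`` most frequent word types with their frequencies.

    Entries are sorted by frequency descending, ties broken
    lexicographically ascending, so builds are reproducible.
    """

    entries: list[tuple[str, int]]
    size_limit: int

    def __post_init__(self):
        self._index = {w: i for i, (w, _) in enumerate(self.entries)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    @property
    def words(self) -> list[str]:
        return [w for w, _ in self.entries]

    def index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise OutOfVocabularyError(word) from None

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word, freq in self.entries:
                fh.write(f"{word}\t{freq}\n")

    @classmethod
    def load_tsv(cls, path: str | Path, size_limit: int | None = None) -> "Vocabulary":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                word, freq = line.rstrip("\n").split("\t")
                entries.append((word, int(freq)))
        return cls(entries, size_limit if size_limit is not None else len(entries))


def build_vocabulary(sentences: Iterable[list[str]], size_limit: int) -> Vocabulary:
    """Select the ``size_limit`` most frequent word types.

    Raises :class:`EmptyCorpusError` when the stream holds no tokens.
    """
    if size_limit < 1:
        raise ValueError("size_limit must be >= 1")
    freqs = Counter()
    for sent in sentences:
        freqs.update(sent)
    if not freqs:
        raise EmptyCorpusError("corpus contains no tokens")
    ranked = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
    return Vocabulary(ranked[:size_limit], size_limit)


@dataclass
class CooccurrenceTable:
    """Sparse windowed co-occurrence counts.

    Rows follow vocabulary rank order; columns are *all* corpus word
    types (contexts are not restricted to the vocabulary), ordered by
    corpus frequency descending then lexicographically. ``row_freq`` and
    ``context_freq`` are full-corpus token frequencies; ``total_W`` is
    the summed frequency of vocabulary words.
    """

    counts: sp.csr_matrix
    row_words: list[str]
    col_words: list[str]
    row_freq: np.ndarray
    context_freq: np.ndarray
    total_W: int
    window: int


def count_cooccurrences(
    sentences: Iterable[list[str]],
    vocab: Vocabulary,
    window: int = 2,
    min_context_count: int = 1,
) -> CooccurrenceTable:
    """Count within-sentence co-occurrences in a symmetric window.

    For each occurrence of a vocabulary word ``w`` at position ``i``,
    every token at positions ``i-window .. i+window`` (excluding ``i``
    itself, never crossing sentence boundaries) contributes one count to
    ``f(w, c)``. A word co-occurring with another occurrence of itself
    is counted. ``min_context_count`` optionally drops context columns
    rarer than the threshold (default 1 = keep everything).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sentences = list(sentences)

    term_freq = Counter()
    for sent in sentences:
        term_freq.update(sent)
    if not term_freq:
        raise EmptyCorpusError("corpus contains no tokens")

    col_types = sorted(
        (w for w, f in term_freq.items() if f >= min_context_count),
        key=lambda w: (-term_freq[w], w),
    )
    col_index = {w: j for j, w in enumerate(col_types)}

    pair_counts: Counter = Counter()
    for sent in sentences:
        n = len(sent)
        for i, tok in enumerate(sent):
            if tok not in vocab:
                continue
            ri = vocab.index(tok)
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                cj = col_index.get(sent[j])
                if cj is not None:
                    pair_counts[(ri, cj)] += 1

    if pair_counts:
        rows, cols = zip(*pair_counts.keys())
        data = list(pair_counts.values())
    else:
        rows, cols, data = [], [], []
    counts = sp.coo_matrix(
        (data, (rows, cols)),
        shape=(len(vocab), len(col_types)),
        dtype=np.int64,
    ).tocsr()

    row_words = vocab.words
    row_freq = np.array([term_freq.get(w, 0) for w in row_words], dtype=np.int64)
    context_freq = np.array([term_freq[c] for c in col_types], dtype=np.int64)
    return CooccurrenceTable(
        counts=counts,
        row_words=row_words,
        col_words=col_types,
        row_freq=row_freq,
        context_freq=context_freq,
        total_W=int(row_freq.sum()),
        window=window,
    )


@dataclass
class PMIMatrix:
    """Sparse non-negative PMI weights; zero means "never co-occurs"."""

    matrix: sp.csr_matrix
    row_words: list[str]
    col_words: list[str]
    _row_index: dict = field(init=False, repr=False)
    _col_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._row_index = {w: i for i, w in enumerate(self.row_words)}
        self._col_index = {c: j for j, c in enumerate(self.col_words)}

    def __contains__(self, word: str) -> bool:
        return word in self._row_index

    def row_index(self, word: str) -> int:
        try:
            return self._row_index[word]
        except KeyError:
            raise OutOfVocabularyError(word) from None

    def row(self, word: str) -> sp.csr_matrix:
        """The 1 x n_contexts sparse PMI row for ``word``."""
        return self.matrix.getrow(self.row_index(word))

    def value(self, word: str, context: str) -> float:
        """PMI(word, context); 0.0 for unknown contexts (never co-occur)."""
        j = self._col_index.get(context)
        if j is None:
            return 0.0
        return float(self.matrix[self.row_index(word), j])

    # --- persistence: MatrixMarket + row/column label TSVs -------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # precision=17 makes the float64 round-trip bit-exact
        mmwrite(str(out / "pmi.mtx"), self.matrix.tocoo(), precision=17)
        for name, labels in (("rows.tsv", self.row_words), ("cols.tsv", self.col_words)):
            with open(out / name, "w", encoding="utf-8") as fh:
                fh.write("".join(f"{w}\n" for w in labels))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PMIMatrix":
        src = Path(in_dir)
        matrix = sp.csr_matrix(mmread(str(src / "pmi.mtx")))
        labels = []
        for name in ("rows.tsv", "cols.tsv"):
            with open(src / name, encoding="utf-8") as fh:
                labels.append([line.rstrip("\n") for line in fh])
        return cls(matrix, labels[0], labels[1])


def compute_pmi(table: CooccurrenceTable, cfg: PMIConfig | None = None) -> PMIMatrix:
    """Apply the smoothed non-negative PMI weighting to a count table.

    Every stored count (necessarily >= 1) maps to a strictly positive
    weight; absent cells stay exactly 0 and are not stored.
    """
    cfg = cfg or PMIConfig()
    if table.total_W <= 0:
        raise InvalidTableError("total vocabulary token count W must be positive")
    if np.any(table.row_freq <= 0):
        bad = [w for w, f in zip(table.row_words, table.row_freq) if f <= 0]
        raise InvalidTableError(f"zero marginal frequency for vocabulary rows: {bad[:5]}")

    coo = table.counts.tocoo()
    ratio = (
        coo.data.astype(np.float64)
        * table.total_W
        / (table.row_freq[coo.row] * (table.context_freq[coo.col] + cfg.smoothing_a))
    )
    values = np.log2(ratio + 1.0)
    matrix = sp.coo_matrix(
        (values, (coo.row, coo.col)), shape=table.counts.shape
    ).tocsr()
    return PMIMatrix(matrix, list(table.row_words), list(table.col_words))
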