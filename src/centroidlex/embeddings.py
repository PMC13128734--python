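"""Word-embedding spaces: loading, normalization, lookup, cosine similarity.

An :class:`EmbeddingSpace` is an ordered vocabulary with one fixed-dimension
vector per word. Word order encodes descending corpus-frequency rank (rank 1
first), which is what frequency-capped reference lexicons are cut from.
Supported on-disk formats are the word2vec text dialect (header line
``"<vocab> <dim>"`` followed by ``word f1 ... fd`` rows) and the headerless
GloVe-style variant of the same table.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_WS_RUN = re.compile(r"\s+")


class _Unmapped:
    """Sentinel for a word the vectorizer cannot map. Falsy; a value, not an error."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "UNMAPPED"


UNMAPPED = _Unmapped()

VectorizePolicy = Literal["exact", "token-average"]


def normalize_token(token: str) -> str:
    """Canonical token form: Unicode NFC, lowercased, outer whitespace
    stripped, internal whitespace runs collapsed to a single space."""
    token = unicodedata.normalize("NFC", token)
    return _WS_RUN.sub(" ", token.strip().lower())


@dataclass
class EmbeddingSpace:
    """Frequency-ordered vocabulary with a d-dimensional vector per word.

    Parameters
    ----------
    words
        Unique token strings, ordered by descending corpus frequency
        (rank 1 first).
    vectors
        Real matrix with ``len(words)`` rows and ``d`` columns. No row may
        be the all-zero vector.
    """

    words: list[str]
    vectors: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)
    _unit: np.ndarray | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        self.words = list(self.words)
        self.vectors = np.ascontiguousarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.words) != self.vectors.shape[0]:
            raise ValueError(
                f"{len(self.words)} words but {self.vectors.shape[0]} vector rows"
            )
        self._index = {w: i for i, w in enumerate(self.words)}
        if len(self._index) != len(self.words):
            raise ValueError("duplicate words in EmbeddingSpace")
        norms = np.linalg.norm(self.vectors, axis=1)
        if len(norms) and not norms.all():
            bad = int(np.flatnonzero(norms == 0.0)[0])
            raise ValueError(f"all-zero vector for word {self.words[bad]!r}")

    @property
    def d(self) -> int:
        """Embedding dimensionality."""
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def index(self, word: str) -> int:
        return self._index[word]

    def get(self, word: str) -> np.ndarray | None:
        i = self._index.get(word)
        return None if i is None else self.vectors[i]

    @property
    def unit_vectors(self) -> np.ndarray:
        """Row-normalized copy of the vector matrix (cached)."""
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            self._unit = self.vectors / norms
        return self._unit

    def lexicon(self, n: int) -> list[str]:
        """The ``n`` most frequent words (a prefix of the ordering)."""
        if n > len(self.words):
            raise ValueError(f"lexicon size {n} exceeds vocabulary {len(self.words)}")
        return self.words[:n]


@dataclass(frozen=True)
class LexiconSpec:
    """A frequency-capped competitor lexicon: the first ``size`` words of the
    space's frequency ordering, or an explicit word list."""

    size: int
    source: str = "space-order"
    words: tuple[str, ...] | None = None

    def resolve(self, space: EmbeddingSpace) -> list[str]:
        if self.words is not None:
            return list(self.words[: self.size])
        return space.lexicon(self.size)


class VectorFormatError(ValueError):
    """Raised for malformed vector-table files."""


def _is_header(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        int(parts[0]), int(parts[1])
    except ValueError:
        return False
    return True


def read_vectors(
    path: str | Path,
    format: Literal["auto", "word2vec-text", "glove-text"] = "auto",
    limit: int | None = None,
    frequency_list: str | Path | None = None,
) -> EmbeddingSpace:
    """Read a word2vec-text or GloVe-style vector table.

    Tokens are normalized (NFC, lowercase, whitespace-collapsed); when two
    rows normalize to the same token the first occurrence wins and the number
    of dropped duplicates is logged. ``limit`` keeps only the first ``limit``
    rows, i.e. the highest-frequency words. ``frequency_list`` (one word per
    line, descending frequency) overrides the file's row order: the space is
    reordered to the list, and words absent from the list are dropped.

    Raises
    ------
    VectorFormatError
        On an empty file or a row whose column count disagrees with the rest
        (the error names the offending line number).
    """
    path = Path(path)
    words: list[str] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    n_dup = 0
    d: int | None = None
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise VectorFormatError(f"{path}: empty vector file")
        lineno = 1
        if format == "word2vec-text" or (format == "auto" and _is_header(first)):
            if not _is_header(first):
                raise VectorFormatError(
                    f"{path}:1: expected word2vec header '<vocab> <dim>'"
                )
            d = int(first.split()[1])
        else:
            _consume_row(first, lineno, path, words, rows, seen)
            d = rows[0].shape[0]
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            if limit is not None and len(words) >= limit:
                break
            if not _consume_row(line, lineno, path, words, rows, seen, d):
                n_dup += 1
            d = rows[0].shape[0]
    if not rows:
        raise VectorFormatError(f"{path}: no vector rows")
    if n_dup:
        logger.warning("%s: dropped %d duplicate word(s), first occurrence kept", path, n_dup)
    space = EmbeddingSpace(words, np.vstack(rows))
    if frequency_list is not None:
        order = [normalize_token(w) for w in Path(frequency_list).read_text(encoding="utf-8").split()]
        keep = [w for w in order if w in space]
        if not keep:
            raise VectorFormatError(f"{frequency_list}: no overlap with vocabulary")
        idx = [space.index(w) for w in keep]
        space = EmbeddingSpace(keep, space.vectors[idx])
    return space


def _consume_row(
    line: str,
    lineno: int,
    path: Path,
    words: list[str],
    rows: list[np.ndarray],
    seen: set[str],
    d: int | None = None,
) -> bool:
    parts = line.rstrip("\n").split()
    if len(parts) < 2:
        raise VectorFormatError(f"{path}:{lineno}: expected 'word f1 ... fd'")
    word = normalize_token(parts[0])
    try:
        vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float64)
    except ValueError as exc:
        raise VectorFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if d is not None and vec.shape[0] != d:
        raise VectorFormatError(
            f"{path}:{lineno}: {vec.shape[0]} columns, expected {d}"
        )
    if word in seen:
        return False
    seen.add(word)
    words.append(word)
    rows.append(vec)
    return True


def write_vectors(
    space: EmbeddingSpace,
    path: str | Path,
    header: bool = True,
    fmt: str = "%.17g",
) -> None:
    """Write the space as word2vec text (``header=True``) or GloVe text.

    The default float format round-trips IEEE doubles exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(space)} {space.d}\n")
        for word, row in zip(space.words, space.vectors):
            fh.write(word + " " + " ".join(fmt % x for x in row) + "\n")


def restrict_to(space: EmbeddingSpace, keep: Iterable[str]) -> EmbeddingSpace:
    """Subspace containing only the words in ``keep``, original order kept."""
    keep = set(keep)
    idx = [i for i, w in enumerate(space.words) if w in keep]
    if not idx:
        raise ValueError("restrict_to: empty intersection with vocabulary")
    return EmbeddingSpace([space.words[i] for i in idx], space.vectors[idx])


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u,v)/(|u||v|); zero-norm input is an error,
    never silently 0."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def vectorize(
    word: str,
    space: EmbeddingSpace,
    policy: VectorizePolicy = "exact",
) -> np.ndarray | _Unmapped:
    """Map an (already-normalized) word string to a vector, or UNMAPPED.

    ``exact``: the word's own row. ``token-average``: mean of the rows of the
    whitespace-split tokens (for multi-word responses such as feature
    phrases); UNMAPPED if any token is missing.
    """
    if policy == "exact":
        v = space.get(word)
        return UNMAPPED if v is None else v
    if policy == "token-average":
        toks = word.split()
        if not toks:
            return UNMAPPED
        vecs = [space.get(t) for t in toks]
        if any(v is None for v in vecs):
            return UNMAPPED
        return np.mean(vecs, axis=0)
    raise ValueError(f"unknown vectorize policy {policy!r}")


def make_vectorizer(
    space: EmbeddingSpace, policy: VectorizePolicy = "exact"
) -> Callable[[str], np.ndarray | _Unmapped]:
    """Bind a space and policy into a ``word -> vector | UNMAPPED`` callable
    (the pluggable meaning-to-vector hook; external subword models can be
    substituted by passing any callable with this signature downstream)."""

    def _vec(word: str) -> np.ndarray | _Unmapped:
        return vectorize(word, space, policy)

    return _vec
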