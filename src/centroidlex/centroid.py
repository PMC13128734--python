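"""Centroid computation: type- or token-weighted means of response vectors.

The centroid (geometric center) of the mapped response vectors is the
estimate of the concept that generated the responses. Token weighting
includes each response as often as it was produced (count-weighted mean);
type weighting includes each unique response once (unweighted mean over
distinct responses).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np

from centroidlex.embeddings import UNMAPPED
from centroidlex.responses import ResponseSet

logger = logging.getLogger(__name__)

Weighting = Literal["type", "token"]


@dataclass
class CentroidResult:
    """A response centroid with its bookkeeping.

    ``vector`` is a convex combination of the mapped response vectors
    (weights >= 0 summing to 1); ``n_unique``/``n_total`` are carried from
    the originating response set.
    """

    target: str
    level: str
    weighting: Weighting
    vector: np.ndarray
    n_unique: int
    n_total: int
    participant: str | None = None


def compute_centroid(
    items: Sequence[tuple[np.ndarray, int]],
    weighting: Weighting = "token",
    normalize_before_average: bool = False,
) -> np.ndarray:
    """Average a multiset of (vector, count) response items.

    type: unweighted mean over distinct items.
    token: count-weighted mean, sum(c_i v_i) / sum(c_i).

    ``normalize_before_average`` L2-normalizes each response vector first
    (the target's neighborhood rank is invariant to centroid scale, but the
    direction of the average can differ when response norms vary).
    """
    if not items:
        raise ValueError("compute_centroid: empty item set")
    d = np.asarray(items[0][0]).shape
    vecs = []
    counts = []
    for v, c in items:
        v = np.asarray(v, dtype=np.float64)
        if v.shape != d:
            raise ValueError(f"dimension mismatch: {v.shape} vs {d}")
        if c < 1:
            raise ValueError("counts must be >= 1")
        if normalize_before_average:
            n = np.linalg.norm(v)
            if n == 0.0:
                raise ValueError("zero-norm response vector")
            v = v / n
        vecs.append(v)
        counts.append(float(c))
    mat = np.vstack(vecs)
    if weighting == "type":
        return mat.mean(axis=0)
    if weighting == "token":
        w = np.asarray(counts)
        return (w @ mat) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def centroid_batch(
    sets: Sequence[ResponseSet],
    vectorizer: Callable[[str], object],
    weighting: Weighting = "token",
    normalize_before_average: bool = False,
) -> list[CentroidResult]:
    """One CentroidResult per ResponseSet, in input order.

    Response sets are expected to be pre-filtered to mappable responses; a
    set in which no response maps is skipped with a log message (its
    bookkeeping would otherwise desynchronize), and a partially mappable set
    is a hard error, since unmapped responses must be excluded upstream.
    """
    out: list[CentroidResult] = []
    for s in sets:
        items = []
        unmapped = []
        for resp, count in s.items.items():
            v = vectorizer(resp)
            if v is UNMAPPED:
                unmapped.append(resp)
            else:
                items.append((np.asarray(v, dtype=np.float64), count))
        if not items:
            logger.warning(
                "centroid_batch: target %r (%s) has no mappable responses; skipped",
                s.target,
                s.participant or s.level,
            )
            continue
        if unmapped:
            raise ValueError(
                f"unmapped responses for target {s.target!r}: {unmapped[:5]} "
                "(run filter_mapped first)"
            )
        vec = compute_centroid(items, weighting, normalize_before_average)
        out.append(
            CentroidResult(
                target=s.target,
                level=s.level,
                weighting=weighting,
                vector=vec,
                n_unique=s.n_unique,
                n_total=s.n_total,
                participant=s.participant,
            )
        )
    return out


def write_centroid_table(
    results: Sequence[CentroidResult],
    path: str | Path,
    include_vectors: bool = False,
) -> None:
    """TSV dump: target, participant, weighting, n_unique, n_total
    (+ d vector columns when requested)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        d = results[0].vector.shape[0] if results else 0
        header = ["target", "participant", "weighting", "n_unique", "n_total"]
        if include_vectors:
            header += [f"v{i}" for i in range(d)]
        fh.write("\t".join(header) + "\n")
        for r in results:
            row = [
                r.target,
                r.participant or "",
                r.weighting,
                str(r.n_unique),
                str(r.n_total),
            ]
            if include_vectors:
                row += ["%.17g" % x for x in r.vector]
            fh.write("\t".join(row) + "\n")
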