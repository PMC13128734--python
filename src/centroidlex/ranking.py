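"""Neighborhood ranks and Hit@k curves.

The target's neighborhood rank within a centroid's semantic neighborhood is
1 + the number of reference-lexicon words whose cosine to the centroid
strictly exceeds the target's cosine. The reference lexicon is the N most
frequent words of the space; the responses themselves (which by task design
cannot be the target) are removed from the competitor set, as is the target
itself. Hit@k is the fraction of targets with rank <= k; by chance a Hit@1
occurs at the base rate p = 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from centroidlex.centroid import CentroidResult
from centroidlex.embeddings import EmbeddingSpace, LexiconSpec

#: cosine differences at or below this are ties and do not increment rank
TIE_TOL = 1e-12


@dataclass
class RankResult:
    """The target's neighborhood rank for one lexicon size.

    ``n_excluded`` counts competitor words removed because they were
    responses (the target's own removal is not counted).
    """

    target: str
    lexicon_size: int
    cosine_to_target: float
    rank: int
    n_excluded: int
    participant: str | None = None
    weighting: str | None = None


@dataclass
class HitCurve:
    """Hit@k for k = 1..k_max: fraction of targets with rank <= k."""

    fractions: dict[int, float]
    n_targets: int


def base_rate(n: int) -> float:
    """Chance probability of a Hit@1 against an N-word lexicon: exactly 1/N."""
    if n < 1:
        raise ValueError("lexicon size must be >= 1")
    return 1.0 / n


def neighborhood_rank(
    centroid: np.ndarray,
    target: str,
    space: EmbeddingSpace,
    lexicon: int | LexiconSpec,
    exclude: Iterable[str] = (),
    tie_tol: float = TIE_TOL,
) -> RankResult:
    """Rank the target among the centroid's nearest lexicon words.

    Competitors are the first N words of the frequency ordering, minus the
    excluded response strings, minus the target itself. The rank is
    1 + #{competitors with cosine > cosine(centroid, target)}; cosine
    differences within ``tie_tol`` are ties and do not increment the rank
    (optimistic / strict-greater counting). The target need not be among the
    top-N words: it is still ranked relative to that lexicon.
    """
    spec = LexiconSpec(lexicon) if isinstance(lexicon, (int, np.integer)) else lexicon
    if target not in space:
        raise KeyError(f"target {target!r} not in embedding space")
    centroid = np.asarray(centroid, dtype=np.float64)
    cnorm = np.linalg.norm(centroid)
    if cnorm == 0.0:
        raise ValueError("centroid has zero norm")
    n = spec.size
    if spec.words is not None:
        comp_idx = np.asarray([space.index(w) for w in spec.resolve(space) if w in space])
    else:
        if n > len(space):
            raise ValueError(f"lexicon size {n} exceeds vocabulary {len(space)}")
        comp_idx = np.arange(n)
    # cosines against unit rows; centroid scale cancels in the comparison
    unit = space.unit_vectors
    c_hat = centroid / cnorm
    cos_target = float(unit[space.index(target)] @ c_hat)
    drop = {space.index(w) for w in exclude if w in space}
    n_excluded = sum(1 for i in drop if i in set(comp_idx.tolist()) and space.words[i] != target)
    drop.add(space.index(target))
    mask = np.isin(comp_idx, list(drop), invert=True) if drop else np.ones(len(comp_idx), bool)
    cos = unit[comp_idx[mask]] @ c_hat
    rank = 1 + int(np.count_nonzero(cos > cos_target + tie_tol))
    return RankResult(
        target=target,
        lexicon_size=n,
        cosine_to_target=cos_target,
        rank=rank,
        n_excluded=n_excluded,
    )


def rank_batch(
    centroids: Sequence[CentroidResult],
    space: EmbeddingSpace,
    lexicon_sizes: Sequence[int],
    exclusions: Mapping[str, Iterable[str]] | None = None,
    tie_tol: float = TIE_TOL,
) -> pd.DataFrame:
    """Neighborhood ranks for many centroids x nested lexicon sizes.

    Cosines are computed once against the largest lexicon; each smaller
    (nested) lexicon reuses the prefix. ``exclusions`` maps target (or, for
    individual-level runs, the (target, participant) pair) -> the response
    strings to drop from its competitor set; by convention the centroid's
    own responses. Returns a long DataFrame with columns target,
    participant, weighting, N, cosine_to_target, rank, n_excluded, n_unique,
    n_total.
    """
    sizes = sorted(set(int(n) for n in lexicon_sizes))
    if not sizes:
        raise ValueError("no lexicon sizes given")
    if sizes[-1] > len(space):
        raise ValueError(f"lexicon size {sizes[-1]} exceeds vocabulary {len(space)}")
    exclusions = exclusions or {}
    unit = space.unit_vectors
    n_max = sizes[-1]
    rows = []
    for cr in centroids:
        if cr.target not in space:
            raise KeyError(f"target {cr.target!r} not in embedding space")
        cnorm = np.linalg.norm(cr.vector)
        if cnorm == 0.0:
            raise ValueError(f"zero-norm centroid for target {cr.target!r}")
        c_hat = cr.vector / cnorm
        t_idx = space.index(cr.target)
        cos_target = float(unit[t_idx] @ c_hat)
        excl_words = exclusions.get((cr.target, cr.participant))
        if excl_words is None:
            excl_words = exclusions.get(cr.target, ())
        excl_idx = np.asarray(
            sorted({space.index(w) for w in excl_words if w in space} - {t_idx}),
            dtype=int,
        )
        cos = unit[:n_max] @ c_hat
        beats = cos > cos_target + tie_tol
        if t_idx < n_max:
            beats[t_idx] = False
        excl_in = excl_idx[excl_idx < n_max] if excl_idx.size else excl_idx
        if excl_in.size:
            beats[excl_in] = False
        cum_beats = np.cumsum(beats)
        for n in sizes:
            rows.append(
                {
                    "target": cr.target,
                    "participant": cr.participant,
                    "weighting": cr.weighting,
                    "N": n,
                    "cosine_to_target": cos_target,
                    "rank": 1 + int(cum_beats[n - 1]),
                    "n_excluded": int(np.count_nonzero(excl_in < n)) if excl_in.size else 0,
                    "n_unique": cr.n_unique,
                    "n_total": cr.n_total,
                }
            )
    return pd.DataFrame(rows)


def hit_at_k(ranks: Sequence[RankResult] | Sequence[int] | np.ndarray, k: int) -> float:
    """Exact fraction of targets with rank <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = _rank_values(ranks)
    if vals.size == 0:
        raise ValueError("hit_at_k: empty rank sequence")
    return float(np.count_nonzero(vals <= k)) / vals.size


def hit_curve(
    ranks: Sequence[RankResult] | Sequence[int] | np.ndarray, k_max: int = 20
) -> HitCurve:
    """Hit@k for k = 1..k_max; non-decreasing in k by construction."""
    vals = _rank_values(ranks)
    if vals.size == 0:
        raise ValueError("hit_curve: empty rank sequence")
    fractions = {
        k: float(np.count_nonzero(vals <= k)) / vals.size for k in range(1, k_max + 1)
    }
    return HitCurve(fractions=fractions, n_targets=int(vals.size))


def _rank_values(ranks) -> np.ndarray:
    if len(ranks) and isinstance(ranks[0], RankResult):
        return np.asarray([r.rank for r in ranks], dtype=int)
    return np.asarray(ranks, dtype=int)


def write_rank_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_hit_curve(curve: HitCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "k": list(curve.fractions),
            "fraction": list(curve.fractions.values()),
            "n_targets": curve.n_targets,
        }
    ).to_csv(path, sep="\t", index=False)
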