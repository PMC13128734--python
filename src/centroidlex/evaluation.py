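"""Hyperparameter sweeps and response-count / individual-level analyses.

Covers the evaluation machinery around centroid recovery:

* crossed sweeps (semantic space x weighting x lexicon size -> Hit@k);
* how neighborhood rank varies with the number of unique/total responses per
  target, via robust local regression (loess, family="symmetric") after
  removing response-count outliers beyond 4 SD (z-score rule), with plateau
  detection (the smallest count at which the fitted rank first drops below a
  rank threshold);
* individual-level curves using only the first m = 1..10 responses per
  participant, and per-participant rank distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from centroidlex.centroid import centroid_batch
from centroidlex.embeddings import EmbeddingSpace, make_vectorizer
from centroidlex.ranking import hit_curve, rank_batch
from centroidlex.responses import ResponseRecord, ResponseSet, aggregate

Family = Literal["gaussian", "symmetric"]

DEFAULT_LEXICON_SIZES = (20000, 50000, 100000, 250000)
PLATEAU_THRESHOLDS = (3, 5, 18)


@dataclass
class SweepConfig:
    """Crossed design for a sweep: named spaces x weightings x lexicon sizes.

    ``spaces`` maps a space name to (EmbeddingSpace, vectorize policy).
    """

    spaces: Mapping[str, tuple[EmbeddingSpace, str]]
    weightings: Sequence[str] = ("type", "token")
    lexicon_sizes: Sequence[int] = DEFAULT_LEXICON_SIZES
    level: str = "group"
    k_max: int = 20

    def __post_init__(self) -> None:
        if not self.spaces or not self.weightings or not len(self.lexicon_sizes):
            raise ValueError("sweep factors must be non-empty")
        for name, (space, _) in self.spaces.items():
            if max(self.lexicon_sizes) > len(space):
                raise ValueError(
                    f"lexicon size {max(self.lexicon_sizes)} exceeds vocabulary "
                    f"of space {name!r} ({len(space)})"
                )


def run_sweep(
    sets: Sequence[ResponseSet],
    config: SweepConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Hit@k over the full crossed design.

    Returns (sweep table, per-cell rank tables). The sweep table has one row
    per space x weighting x N x k; every Hit@k cell is computed from the
    rank table of the same (space, weighting) cell, whose responses are
    excluded from the competitor sets. Deterministic for fixed inputs.
    """
    exclusions = {s.target: set(s.items) for s in sets}
    rows = []
    rank_tables: dict[str, pd.DataFrame] = {}
    for space_name in sorted(config.spaces):
        space, policy = config.spaces[space_name]
        vec = make_vectorizer(space, policy)  # type: ignore[arg-type]
        for weighting in config.weightings:
            cents = centroid_batch(sets, vec, weighting)  # type: ignore[arg-type]
            table = rank_batch(cents, space, config.lexicon_sizes, exclusions)
            rank_tables[f"{space_name}_{weighting}"] = table
            for n, sub in table.groupby("N"):
                curve = hit_curve(sub["rank"].to_numpy(), k_max=config.k_max)
                for k, frac in curve.fractions.items():
                    rows.append(
                        {
                            "space": space_name,
                            "weighting": weighting,
                            "N": int(n),
                            "k": k,
                            "hit_at_k": frac,
                            "n_targets": curve.n_targets,
                        }
                    )
    return pd.DataFrame(rows), rank_tables


def remove_count_outliers(
    counts: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    threshold_sd: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop (count, value) pairs whose COUNT is a z-score outlier.

    z is computed from the count variable's mean and sample SD (n-1);
    points with |z| >= threshold_sd are removed. With fewer than 2 points or
    zero SD the input is returned unchanged. Returns (counts, values, kept
    mask); removal is invariant to point order.
    """
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts.shape != values.shape:
        raise ValueError("counts and values must align")
    if counts.size < 2:
        return counts, values, np.ones_like(counts, dtype=bool)
    sd = counts.std(ddof=1)
    if sd == 0.0:
        return counts, values, np.ones_like(counts, dtype=bool)
    z = (counts - counts.mean()) / sd
    keep = np.abs(z) < threshold_sd
    return counts[keep], values[keep], keep


def _local_fit(
    x: np.ndarray,
    y: np.ndarray,
    delta: np.ndarray,
    x0: float,
    q: int,
) -> float:
    """Tricube-weighted degree-1 fit at x0 over the q nearest points."""
    dist = np.abs(x - x0)
    h = np.partition(dist, q - 1)[q - 1]
    if h <= 0.0:
        w = (dist == 0.0) * delta
        if w.sum() <= 0.0:
            w = delta.copy()
    else:
        u = np.clip(dist / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3 * delta
        if w.sum() <= 0.0:  # every in-window point robustness-zeroed
            w = (1.0 - u**3) ** 3
    xc = x - x0
    sw = w.sum()
    swx = (w * xc).sum()
    swy = (w * y).sum()
    swxx = (w * xc * xc).sum()
    swxy = (w * xc * y).sum()
    denom = sw * swxx - swx * swx
    # degenerate window (all x equal or rank-deficient): local weighted mean
    if denom <= 1e-12 * max(sw * swxx, 1e-300):
        return swy / sw
    beta1 = (sw * swxy - swx * swy) / denom
    beta0 = (swy - beta1 * swx) / sw
    return beta0


def loess_fit(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    span: float = 0.75,
    degree: int = 1,
    family: Family = "symmetric",
    iterations: int = 4,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
) -> pd.DataFrame:
    """Locally weighted regression on a fixed evaluation grid.

    At each grid point the ceil(span*n) nearest data points (by |x - x0|)
    enter a tricube-weighted linear fit. family="symmetric" additionally
    runs ``iterations`` robustness passes that reweight points by the
    bisquare of their scaled residuals (scale = 6 * median |residual|),
    down-weighting y-outliers; family="gaussian" fits once with no
    robustness reweighting. Returns a DataFrame with columns x, y_fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D arrays")
    n = x.size
    q = int(math.ceil(span * n))
    if n < max(3, q) or q < 2:
        raise ValueError(f"loess needs at least max(3, ceil(span*n)) points, got {n}")
    if degree != 1:
        raise NotImplementedError("only degree-1 (local linear) loess is provided")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    delta = np.ones(n)
    if family == "symmetric":
        for _ in range(iterations):
            fitted = np.array([_local_fit(xs, ys, delta, x0, q) for x0 in xs])
            resid = ys - fitted
            s = 6.0 * np.median(np.abs(resid))
            if s <= 0.0:
                break
            u = resid / s
            delta = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    elif family != "gaussian":
        raise ValueError(f"unknown family {family!r}")
    if grid is None:
        grid = np.linspace(xs[0], xs[-1], n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    y_fit = np.array([_local_fit(xs, ys, delta, x0, q) for x0 in grid])
    return pd.DataFrame({"x": grid, "y_fit": y_fit})


def response_count_curve(
    rank_table: pd.DataFrame,
    count_kind: Literal["unique", "total"],
    thresholds: Sequence[float] = PLATEAU_THRESHOLDS,
    span: float = 0.75,
    family: Family = "symmetric",
    iterations: int = 4,
    outlier_sd: float = 4.0,
    n_grid: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Smoothed neighborhood rank vs. responses-per-target, with plateaus.

    Applies the count-outlier rule, then robust loess of rank on the count,
    and reports for each rank threshold the smallest count at which the
    fitted curve first drops to or below it ("responses per target needed").
    Grid spacing is reported as the uncertainty of each plateau count; a
    curve that never crosses a threshold yields ``None`` ("not reached").
    """
    col = "n_unique" if count_kind == "unique" else "n_total"
    counts = rank_table[col].to_numpy(dtype=float)
    ranks = rank_table["rank"].to_numpy(dtype=float)
    counts, ranks, _ = remove_count_outliers(counts, ranks, outlier_sd)
    curve = loess_fit(
        counts, ranks, span=span, family=family, iterations=iterations, n_grid=n_grid
    )
    step = float(curve["x"].iloc[1] - curve["x"].iloc[0]) if len(curve) > 1 else 0.0
    plateaus: dict = {"count_kind": count_kind, "grid_step": step, "thresholds": {}}
    for thr in thresholds:
        below = curve.index[curve["y_fit"] <= thr]
        plateaus["thresholds"][str(thr)] = (
            None if len(below) == 0 else float(curve["x"].iloc[below[0]])
        )
    return curve, plateaus


def individual_first_m_curve(
    records: Sequence[ResponseRecord],
    space: EmbeddingSpace,
    policy: str = "exact",
    weighting: str = "token",
    lexicon_size: int | None = None,
    m_max: int = 10,
    k_max: int = 20,
) -> pd.DataFrame:
    """Hit@k using only each participant's first m responses, m = 1..m_max.

    For each m, centroids are recomputed per (target, participant) from the
    responses with position <= m; Hit@k is taken over all pairs that retain
    at least one response at that m (pairs with none are excluded from the
    denominator). Columns: m, k, hit_at_k, n_pairs.
    """
    if lexicon_size is None:
        lexicon_size = len(space)
    vec = make_vectorizer(space, policy)  # type: ignore[arg-type]
    rows = []
    for m in range(1, m_max + 1):
        kept = [r for r in records if r.position <= m]
        sets = aggregate(kept, "individual")
        if not sets:
            continue
        exclusions = {(s.target, s.participant): set(s.items) for s in sets}
        cents = centroid_batch(sets, vec, weighting)  # type: ignore[arg-type]
        table = rank_batch(cents, space, [lexicon_size], exclusions)
        curve = hit_curve(table["rank"].to_numpy(), k_max=k_max)
        for k, frac in curve.fractions.items():
            rows.append(
                {"m": m, "k": k, "hit_at_k": frac, "n_pairs": curve.n_targets}
            )
    return pd.DataFrame(rows)


def participant_rank_summary(
    rank_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant mean/median neighborhood rank, plus the distribution
    of per-participant mean ranks across participants (type-7 quartiles)."""
    if "participant" not in rank_table.columns or rank_table["participant"].isna().all():
        raise ValueError("participant_rank_summary needs individual-level ranks")
    per = (
        rank_table.groupby("participant")["rank"]
        .agg(mean_rank="mean", median_rank="median", n_targets="size")
        .reset_index()
    )
    means = per["mean_rank"].to_numpy(dtype=float)
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    quart = np.quantile(means, qs, method="linear")
    summary = pd.DataFrame(
        {
            "statistic": ["min", "q1", "median", "q3", "max"],
            "mean_rank": quart,
        }
    )
    return per, summary
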