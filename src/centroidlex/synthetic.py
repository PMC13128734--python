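"""Synthetic semantic spaces and spreading-activation response simulation.

The generative story being inverted by centroid analysis: a cue activates
its concept in semantic space and activation spreads evenly in all
directions, surfacing nearby words as responses. The minimal quantitative
model consistent with that account is implemented here: responses are the
vocabulary words nearest (by cosine) to isotropically perturbed copies of
the target vector. Running the full pipeline on such worlds validates
recovery without any external downloads.

Vocabularies are i.i.d. unit vectors uniform on the sphere; the frequency
rank of a synthetic word is simply its generation index (arbitrary, but it
is what lexicon truncation cuts on).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from centroidlex.centroid import centroid_batch
from centroidlex.embeddings import EmbeddingSpace, make_vectorizer
from centroidlex.ranking import hit_curve, rank_batch
from centroidlex.responses import ResponseRecord, aggregate


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a recovery experiment.

    noise_sd is the per-coordinate SD of the isotropic Gaussian perturbation
    added to the (unit-norm) target vector before snapping to the nearest
    word; it plays the role of spreading-activation breadth.
    """

    vocab_size: int = 1000
    dim: int = 50
    n_targets: int = 100
    responses_per_target: int = 10
    noise_sd: float = 0.05
    n_participants: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size <= self.responses_per_target:
            raise ValueError("vocab_size must exceed responses_per_target")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticWorld:
    """A generated space plus ground-truth targets and simulated responses."""

    space: EmbeddingSpace
    targets: list[str]
    records: list[ResponseRecord]
    config: SyntheticConfig


def make_space(vocab_size: int, dim: int, seed: int) -> EmbeddingSpace:
    """Vocabulary of ``vocab_size`` distinct words ("w000001", ...) with rows
    i.i.d. uniform on the unit sphere (Gaussian draw, L2-normalized)."""
    if vocab_size < 2 or dim < 2:
        raise ValueError("need vocab_size >= 2 and dim >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mat = rng.standard_normal((vocab_size, dim))
    mat /= np.linalg.norm(mat, axis=1, keepdims=True)
    words = [f"w{i + 1:06d}" for i in range(vocab_size)]
    return EmbeddingSpace(words, mat)


def simulate_responses(
    space: EmbeddingSpace,
    target: str,
    m: int,
    noise_sd: float,
    seed: int | np.random.SeedSequence,
    exclude_target: bool = True,
    participant: str = "P0",
) -> list[ResponseRecord]:
    """Draw ``m`` responses for ``target`` by spreading activation.

    Each response is the vocabulary word (excluding the target itself when
    ``exclude_target``, mirroring the taboo design) nearest by cosine to
    ``v_target + eps`` with eps ~ Normal(0, noise_sd^2 I). Duplicates occur
    naturally, giving rise to token counts; positions run 1..m.
    """
    if target not in space:
        raise KeyError(f"target {target!r} not in space")
    rng = np.random.default_rng(seed)
    t_idx = space.index(target)
    probes = space.vectors[t_idx] + noise_sd * rng.standard_normal((m, space.d))
    # argmax of cosine is invariant to probe norm, so probes stay unnormalized;
    # a zero probe has measure zero and would tie everything at 0 anyway
    cos = space.unit_vectors @ probes.T  # (V, m)
    if exclude_target:
        cos[t_idx, :] = -np.inf
    picks = np.argmax(cos, axis=0)
    return [
        ResponseRecord(target, space.words[int(j)], participant, pos + 1)
        for pos, j in enumerate(picks)
    ]


def _target_stream(seed: int, key: int) -> np.random.SeedSequence:
    # counter-based splitting: deterministic independent stream per target
    return np.random.SeedSequence(entropy=seed, spawn_key=(key,))


def make_world(
    config: SyntheticConfig,
    level: Literal["group", "individual"] = "group",
) -> SyntheticWorld:
    """Generate a space and simulate responses for ``n_targets`` targets.

    Group level: ``responses_per_target`` responses pooled under one
    notional participant per target. Individual level: every one of
    ``n_participants`` participants produces ``responses_per_target``
    responses for every target, each from its own derived random stream.
    """
    space = make_space(config.vocab_size, config.dim, config.seed)
    pick_rng = np.random.default_rng(_target_stream(config.seed, 0))
    t_idx = pick_rng.choice(config.vocab_size, size=config.n_targets, replace=False)
    targets = [space.words[int(i)] for i in sorted(t_idx)]
    records: list[ResponseRecord] = []
    for ti, target in enumerate(targets, start=1):
        if level == "group":
            records.extend(
                simulate_responses(
                    space,
                    target,
                    config.responses_per_target,
                    config.noise_sd,
                    _target_stream(config.seed, ti),
                )
            )
        else:
            for p in range(config.n_participants):
                records.extend(
                    simulate_responses(
                        space,
                        target,
                        config.responses_per_target,
                        config.noise_sd,
                        _target_stream(config.seed, ti * 100003 + p + 1),
                        participant=f"P{p + 1:03d}",
                    )
                )
    return SyntheticWorld(space, targets, records, config)


def recovery_experiment(
    config: SyntheticConfig,
    noise_levels: Sequence[float] | None = None,
    response_counts: Sequence[int] | None = None,
    weightings: Sequence[str] = ("token",),
    lexicon_sizes: Sequence[int] | None = None,
    ks: Sequence[int] = (1, 5, 20),
) -> pd.DataFrame:
    """Full-pipeline recovery table over noise x response count x weighting
    x lexicon size.

    For each noise level, a world is simulated with the maximal response
    count; each smaller count m reuses the first m positions (so the m-sweep
    measures the value of additional responses, not fresh sampling noise).
    The pipeline is the real one: aggregate -> centroid -> rank -> Hit@k.
    Columns: noise_sd, m, weighting, N, hit@k..., mean_rank, median_rank,
    n_targets. Deterministic for a fixed config seed.
    """
    noise_levels = list(noise_levels) if noise_levels is not None else [config.noise_sd]
    response_counts = (
        sorted(response_counts)
        if response_counts is not None
        else [config.responses_per_target]
    )
    lexicon_sizes = (
        list(lexicon_sizes) if lexicon_sizes is not None else [config.vocab_size]
    )
    m_max = max(response_counts)
    rows = []
    for sigma in noise_levels:
        world = make_world(
            replace(config, noise_sd=sigma, responses_per_target=m_max)
        )
        vec = make_vectorizer(world.space)
        by_target: dict[str, list[ResponseRecord]] = {}
        for rec in world.records:
            by_target.setdefault(rec.target, []).append(rec)
        for m in response_counts:
            kept = [r for recs in by_target.values() for r in recs if r.position <= m]
            sets = aggregate(kept, "group")
            exclusions = {s.target: set(s.items) for s in sets}
            for weighting in weightings:
                cents = centroid_batch(sets, vec, weighting)  # type: ignore[arg-type]
                table = rank_batch(cents, world.space, lexicon_sizes, exclusions)
                for n, sub in table.groupby("N"):
                    ranks = sub["rank"].to_numpy()
                    curve = hit_curve(ranks, k_max=max(ks))
                    row = {
                        "noise_sd": sigma,
                        "m": m,
                        "weighting": weighting,
                        "N": int(n),
                        "mean_rank": float(ranks.mean()),
                        "median_rank": float(np.median(ranks)),
                        "n_targets": len(ranks),
                    }
                    for k in ks:
                        row[f"hit@{k}"] = curve.fractions[k]
                    rows.append(row)
    return pd.DataFrame(rows)
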