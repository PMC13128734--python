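"""Target–response tables: reading, normalization, exclusion, aggregation.

Long-format input: one row per produced response with columns target,
response, participant, position. Aggregation pools responses either across
participants (group level, one multiset per target) or per participant
(individual level, one multiset per target x participant).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from centroidlex.embeddings import UNMAPPED, normalize_token

logger = logging.getLogger(__name__)

Level = Literal["group", "individual"]

DEFAULT_COLUMNS = {
    "target": "target",
    "response": "response",
    "participant": "participant_id",
    "position": "response_position",
}


@dataclass(frozen=True)
class ResponseRecord:
    """One produced response: a normalized (target, response) pair with the
    producing participant and the within-trial production position (1-based)."""

    target: str
    response: str
    participant: str = "P0"
    position: int = 1

    def __post_init__(self) -> None:
        if not self.target or not self.response:
            raise ValueError("target and response must be non-empty")
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class ResponseSet:
    """A target's aggregated response multiset at group or individual level.

    ``items`` maps response string -> production count. ``n_unique`` is the
    number of distinct responses, ``n_total`` the number of productions.
    """

    target: str
    level: Level
    items: dict[str, int]
    participant: str | None = None

    def __post_init__(self) -> None:
        if self.level == "individual" and self.participant is None:
            raise ValueError("individual-level ResponseSet needs a participant")
        if any(c < 1 for c in self.items.values()):
            raise ValueError("counts must be >= 1")

    @property
    def n_unique(self) -> int:
        return len(self.items)

    @property
    def n_total(self) -> int:
        return sum(self.items.values())


@dataclass
class ExclusionReport:
    """Bookkeeping for records removed because the target or response had no
    vector (or the response echoed the target)."""

    n_targets_dropped: int = 0
    n_responses_dropped: int = 0
    dropped_targets: list[str] = field(default_factory=list)
    dropped_response_examples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


def read_long_table(
    path: str | Path,
    dialect: Literal["csv", "tsv", "auto"] = "auto",
    column_map: dict[str, str] | None = None,
) -> list[ResponseRecord]:
    """Read a long-format response table.

    ``column_map`` maps the logical names {target, response, participant,
    position} to the file's column names. The participant and position
    columns are optional: missing participant defaults to the singleton
    "P0"; missing position defaults to a running 1..k position within each
    (target, participant) trial, in file order. Rows with an empty target or
    response are dropped with a logged count.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if dialect == "auto":
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    df = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",", dtype=str)
    for logical in ("target", "response"):
        if cols[logical] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[logical]!r}")
    out: list[ResponseRecord] = []
    n_empty = 0
    positions: dict[tuple[str, str], int] = {}
    has_part = cols["participant"] in df.columns
    has_pos = cols["position"] in df.columns
    for row in df.to_dict("records"):
        target = normalize_token(str(row[cols["target"]]) if pd.notna(row[cols["target"]]) else "")
        response = normalize_token(str(row[cols["response"]]) if pd.notna(row[cols["response"]]) else "")
        if not target or not response:
            n_empty += 1
            continue
        participant = str(row[cols["participant"]]) if has_part and pd.notna(row[cols["participant"]]) else "P0"
        if has_pos and pd.notna(row[cols["position"]]):
            position = int(float(row[cols["position"]]))
        else:
            key = (target, participant)
            positions[key] = positions.get(key, 0) + 1
            position = positions[key]
        out.append(ResponseRecord(target, response, participant, position))
    if n_empty:
        logger.warning("%s: dropped %d empty row(s)", path, n_empty)
    return out


def filter_mapped(
    records: Sequence[ResponseRecord],
    vectorizer: Callable[[str], object],
    drop_target_equal_response: bool = True,
) -> tuple[list[ResponseRecord], ExclusionReport]:
    """Drop records whose response is UNMAPPED, all records of any target
    that is itself UNMAPPED, and (by default) echo responses equal to their
    target. Returns surviving records plus an exact accounting."""
    report = ExclusionReport()
    cache: dict[str, bool] = {}

    def mapped(word: str) -> bool:
        if word not in cache:
            cache[word] = vectorizer(word) is not UNMAPPED
        return cache[word]

    bad_targets = {r.target for r in records if not mapped(r.target)}
    report.dropped_targets = sorted(bad_targets)
    report.n_targets_dropped = len(bad_targets)
    out: list[ResponseRecord] = []
    for rec in records:
        if rec.target in bad_targets:
            report.n_responses_dropped += 1
            continue
        if drop_target_equal_response and rec.response == rec.target:
            report.n_responses_dropped += 1
            if len(report.dropped_response_examples) < 20:
                report.dropped_response_examples.append(rec.response)
            continue
        if not mapped(rec.response):
            report.n_responses_dropped += 1
            if len(report.dropped_response_examples) < 20:
                report.dropped_response_examples.append(rec.response)
            continue
        out.append(rec)
    return out, report


def aggregate(
    records: Sequence[ResponseRecord], level: Level = "group"
) -> list[ResponseSet]:
    """Aggregate records into response multisets.

    Group level: one set per target pooling all participants, count = number
    of times the response string occurs. Individual level: one set per
    (target, participant); a participant repeating a response keeps count > 1.
    Output order follows first appearance in ``records`` (deterministic).
    """
    sets: dict[tuple, dict[str, int]] = {}
    for rec in records:
        key = (rec.target,) if level == "group" else (rec.target, rec.participant)
        items = sets.setdefault(key, {})
        items[rec.response] = items.get(rec.response, 0) + 1
    out = []
    for key, items in sets.items():
        if level == "group":
            out.append(ResponseSet(key[0], "group", items))
        else:
            out.append(ResponseSet(key[0], "individual", items, participant=key[1]))
    return out


def count_summary(sets: Sequence[ResponseSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-target (n_unique, n_total) table plus cross-target quartiles.

    Quartiles use linear interpolation between order statistics (type-7),
    the convention reported alongside the response-count distributions.
    """
    rows = [
        {
            "target": s.target,
            "participant": s.participant,
            "n_unique": s.n_unique,
            "n_total": s.n_total,
        }
        for s in sets
    ]
    per_target = pd.DataFrame(rows, columns=["target", "participant", "n_unique", "n_total"])
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    summary_rows = []
    for col in ("n_unique", "n_total"):
        vals = per_target[col].to_numpy(dtype=float)
        quart = (
            np.quantile(vals, qs, method="linear")
            if len(vals)
            else [np.nan] * len(qs)
        )
        summary_rows.append(
            {
                "variable": col,
                "min": quart[0],
                "q1": quart[1],
                "median": quart[2],
                "q3": quart[3],
                "max": quart[4],
            }
        )
    return per_target, pd.DataFrame(summary_rows)
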