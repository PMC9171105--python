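"""Plain-text serialization of logs, layouts and tables.

Attempt logs are stored either as a flat CSV table (``.csv``) or as
line-delimited JSON records (``.jsonl``); the dialect is auto-detected
from the file extension.  Board layouts are small YAML documents.  All
round-trips are identities.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from ..task_model import (
    Attempt,
    AttemptLog,
    BlockPosition,
    BoardLayout,
    Condition,
)

LOG_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "condition",
    "attempt_index",
    "first_row",
    "first_col",
    "second_row",
    "second_col",
    "first_sound",
    "second_sound",
    "matched",
]


class LogParseError(ValueError):
    """A log file row could not be parsed; carries the line number."""

    def __init__(self, path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


def _log_rows(log: AttemptLog) -> list[dict]:
    return [
        {
            "subject_id": log.subject_id if log.subject_id is not None else "",
            "group": log.group if log.group is not None else "",
            "age": log.age if log.age is not None else "",
            "condition": log.condition.name,
            "attempt_index": a.index,
            "first_row": a.first.row,
            "first_col": a.first.col,
            "second_row": a.second.row,
            "second_col": a.second.col,
            "first_sound": a.first_sound,
            "second_sound": a.second_sound,
            "matched": int(a.matched),
        }
        for a in log.attempts
    ]


def write_log(log: AttemptLog, path: Union[str, Path]) -> None:
    path = Path(path)
    rows = _log_rows(log)
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def _parse_row(row: dict, path, line: int) -> tuple[dict, Attempt]:
    try:
        attempt = Attempt(
            index=int(row["attempt_index"]),
            first=BlockPosition(int(row["first_row"]), int(row["first_col"])),
            second=BlockPosition(int(row["second_row"]), int(row["second_col"])),
            first_sound=str(row["first_sound"]),
            second_sound=str(row["second_sound"]),
            matched=bool(int(row["matched"])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise LogParseError(path, line, f"malformed attempt record: {exc}") from None
    return row, attempt


def read_log(path: Union[str, Path]) -> AttemptLog:
    """Read one session log; raises :class:`LogParseError` on bad rows."""
    path = Path(path)
    raw_rows: list[tuple[int, dict]] = []
    if path.suffix == ".jsonl":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    raw_rows.append((line_no, json.loads(line)))
                except json.JSONDecodeError as exc:
                    raise LogParseError(path, line_no, str(exc)) from None
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(LOG_COLUMNS) - set(df.columns)
        if missing:
            raise LogParseError(path, 1, f"missing columns: {sorted(missing)}")
        # header is line 1
        raw_rows = [(i + 2, row) for i, row in enumerate(df.to_dict("records"))]
    if not raw_rows:
        raise LogParseError(path, 1, "empty log file")

    first = raw_rows[0][1]
    try:
        condition = Condition.from_name(str(first["condition"]))
    except (KeyError, ValueError) as exc:
        raise LogParseError(path, raw_rows[0][0], str(exc)) from None
    subject_id = str(first.get("subject_id") or "") or None
    group = str(first.get("group") or "") or None
    age_raw = first.get("age", "")
    age = float(age_raw) if age_raw not in ("", None) else None

    attempts = []
    for line_no, row in raw_rows:
        _, attempt = _parse_row(row, path, line_no)
        attempts.append(attempt)
    return AttemptLog(condition, attempts, subject_id, group, age)


def write_layout(layout: BoardLayout, path: Union[str, Path]) -> None:
    doc = {
        "condition": layout.condition.name,
        "n_pairs": layout.condition.n_pairs,
        "sounds": list(layout.condition.sounds),
        "seed": layout.seed,
        "apertures": [[p.row, p.col] for p in layout.apertures],
        "assignment": {
            f"{p.row},{p.col}": layout.assignment[p] for p in layout.apertures
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_layout(path: Union[str, Path]) -> BoardLayout:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    condition = Condition(doc["condition"], doc["n_pairs"], tuple(doc["sounds"]))
    apertures = tuple(BlockPosition(r, c) for r, c in doc["apertures"])
    assignment = {}
    for key, sound in doc["assignment"].items():
        r, c = (int(v) for v in key.split(","))
        assignment[BlockPosition(r, c)] = sound
    layout = BoardLayout(condition, apertures, assignment, int(doc["seed"]))
    layout.validate()
    return layout


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)
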