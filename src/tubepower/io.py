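"""Reading and writing tube-level bioassay CSV files.

Files are delimited text with a header row; one row per tube. The
reader is mapping-driven because deposited datasets name their columns
differently; unknown extra columns are preserved as pass-through
metadata on each observation. ``day_id`` is assigned from the distinct
values of the day/date column in chronological order (1-based).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .design import ARMS, REFERENCE, TubeObservation

CSV_COLUMNS = ["day_id", "tube_id", "arm", "n_exposed", "n_dead"]


@dataclass(frozen=True)
class ColumnMapping:
    """Names of the source columns; ``arm=None`` marks single-arm data
    (valid for variance estimation, not for the two-arm test)."""

    day: str = "day_id"
    tube: str = "tube_id"
    arm: str | None = "arm"
    exposed: str = "n_exposed"
    dead: str = "n_dead"
    date_format: str | None = None

    def __post_init__(self) -> None:
        mapped = [c for c in (self.day, self.tube, self.arm, self.exposed, self.dead) if c]
        if len(set(mapped)) != len(mapped):
            raise ValueError("mapped columns must be distinct")


def _day_ids(raw: pd.Series, date_format: str | None) -> pd.Series:
    """Map distinct day values to 1..D in chronological order."""
    try:
        parsed = pd.to_datetime(raw, format=date_format)
    except (ValueError, TypeError):
        parsed = pd.to_numeric(raw, errors="coerce")
        if parsed.isna().any():
            parsed = raw.astype(str)
    order = {v: i + 1 for i, v in enumerate(sorted(parsed.unique()))}
    return parsed.map(order)


def read_tube_csv(path, mapping: ColumnMapping | None = None) -> list[TubeObservation]:
    """Read tube observations from a CSV file.

    Raises on a missing file, an empty file, missing mapped columns, or
    rows violating ``0 <= dead <= exposed`` (the message names the
    offending row, counting the header as row 1).
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: file is empty") from exc
    if len(frame) == 0:
        raise ValueError(f"{path}: no data rows")
    required = [c for c in (mapping.day, mapping.tube, mapping.exposed, mapping.dead) if c]
    if mapping.arm is not None:
        required.append(mapping.arm)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")

    day_ids = _day_ids(frame[mapping.day], mapping.date_format)
    extra_cols = [c for c in frame.columns if c not in required]
    observations = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        row_no = pos + 2  # header is row 1
        try:
            exposed = int(row[mapping.exposed])
            dead = int(row[mapping.dead])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {row_no}: non-integer count") from exc
        arm = str(row[mapping.arm]) if mapping.arm is not None else REFERENCE
        if arm not in ARMS:
            raise ValueError(
                f"{path}: row {row_no}: arm must be one of {ARMS}, got {arm!r}"
            )
        try:
            obs = TubeObservation(
                day_id=int(day_ids.iloc[pos]),
                tube_id=str(row[mapping.tube]),
                arm=arm,
                n_exposed=exposed,
                n_dead=dead,
                extra={c: row[c] for c in extra_cols} or None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
        observations.append(obs)
    return observations


def write_tube_csv(observations: Iterable[TubeObservation], path) -> None:
    """Write observations as CSV with the canonical header (the reader's
    default mapping round-trips it)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for obs in observations:
            writer.writerow([obs.day_id, obs.tube_id, obs.arm, obs.n_exposed, obs.n_dead])
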