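"""Panel file format and run configuration.

Panels travel as comma-delimited text with header ``state,race,year,rate``;
race is stored as the words ``black``/``white`` and mapped to the internal
0/1 coding (1 = White) at parse time.  Years are calendar years; model time
t = year - 1974 is attached on read so 1975 maps to t = 1.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import pandas as pd
import yaml

from .simulate import TIME_ORIGIN

__all__ = ["read_panel", "write_panel", "RunConfig", "PanelFormatError"]

logger = logging.getLogger(__name__)

PANEL_HEADER = ["state", "race", "year", "rate"]
RACE_TO_INT = {"black": 0, "white": 1}
INT_TO_RACE = {0: "black", 1: "white"}


class PanelFormatError(ValueError):
    """A panel file violated the format contract (message cites the line)."""


def read_panel(path: str | Path, time_origin: int = TIME_ORIGIN) -> pd.DataFrame:
    """Read and validate a panel file into the internal long format.

    Returns a DataFrame with columns subject, race (0/1), year, t, rate.
    Violations (bad header, unparseable row, negative rate, duplicate
    (state, race, year) key) raise PanelFormatError naming the line number.
    """
    path = Path(path)
    rows = []
    seen: set[tuple[str, str, int]] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise PanelFormatError(f"{path}: empty file") from None
        if [h.strip() for h in header] != PANEL_HEADER:
            raise PanelFormatError(
                f"{path}:1: header must be {','.join(PANEL_HEADER)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise PanelFormatError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            state, race_s, year_s, rate_s = (f.strip() for f in row)
            if race_s.lower() not in RACE_TO_INT:
                raise PanelFormatError(
                    f"{path}:{lineno}: race must be black or white, got {race_s!r}"
                )
            try:
                year = int(year_s)
                rate = float(rate_s)
            except ValueError:
                raise PanelFormatError(f"{path}:{lineno}: unparseable row {row!r}") from None
            if rate < 0:
                raise PanelFormatError(f"{path}:{lineno}: negative rate {rate}")
            if year <= time_origin:
                raise PanelFormatError(
                    f"{path}:{lineno}: year {year} not after time origin {time_origin}"
                )
            key = (state, race_s.lower(), year)
            if key in seen:
                raise PanelFormatError(
                    f"{path}:{lineno}: duplicate (state, race, year) key {key}"
                )
            seen.add(key)
            rows.append(
                {
                    "subject": state,
                    "race": RACE_TO_INT[race_s.lower()],
                    "year": year,
                    "t": float(year - time_origin),
                    "rate": rate,
                }
            )
    if not rows:
        raise PanelFormatError(f"{path}: no data rows")
    panel = pd.DataFrame(rows)
    logger.info("read %d rows from %s", len(panel), path)
    return panel


def write_panel(panel: pd.DataFrame, path: str | Path) -> Path:
    """Write a panel deterministically: canonical columns, stable sort.

    Rows are sorted by (state, race, year); rates are written with Python's
    shortest round-tripping float representation so write -> read is exact.
    An empty panel produces a header-only file.
    """
    path = Path(path)
    cols = {"subject", "race", "year", "rate"}
    if len(panel) > 0 and not cols.issubset(panel.columns):
        raise ValueError(f"panel must have columns {sorted(cols)}")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PANEL_HEADER)
        if len(panel) > 0:
            ordered = panel.sort_values(["subject", "race", "year"], kind="mergesort")
            for r in ordered.itertuples():
                writer.writerow(
                    [r.subject, INT_TO_RACE[int(r.race)], int(r.year), repr(float(r.rate))]
                )
    logger.info("wrote %d rows to %s", len(panel), path)
    return path


@dataclass
class RunConfig:
    """Plain-text (YAML) key-value run configuration.

    Unknown keys are rejected so that typos fail loudly; the effective
    config is echoed to the log at the start of every run.
    """

    time_origin: int = TIME_ORIGIN
    nodes: int = 7
    maxiter: int = 500
    restarts: int = 3
    df: int | None = None
    level: float = 0.95
    seed: int = 0
    ratio_decimals: int = 2
    decline_decimals: int = 0
    cv_decimals: int = 2
    outdir: str = "."

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def log_effective(self) -> None:
        logger.info("effective config: %s", self.__dict__)
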