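"""Descriptive summaries and disparity metrics over panels and curves.

Summary tables follow the eight-column layout (mean, standard deviation,
CV, minimum, lower quartile, median, upper quartile, maximum) used in the
reference analysis; quartiles use linear interpolation of the empirical CDF
(the common "type 7" convention).  Reporting precision follows the printed
convention: ratios to 2 decimals, percent declines to the nearest integer,
CV to 2 decimals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fit import validate_panel

__all__ = [
    "summarize",
    "cv",
    "rate_ratio",
    "percent_decline",
    "rank_states",
    "mortality_rate",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("mean", "sd", "cv", "min", "q1", "median", "q3", "max")


def cv(mean: float, sd: float) -> float:
    """Coefficient of variation: the SD as a percentage of the mean."""
    if not mean > 0:
        raise ValueError(f"cv requires mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be nonnegative, got {sd}")
    return 100.0 * sd / mean


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """Ratio of two rates (e.g. Black over White mortality)."""
    if rate_b == 0:
        raise ValueError("rate_ratio denominator must be nonzero")
    return rate_a / rate_b


def percent_decline(rate_start: float, rate_end: float) -> float:
    """Percent fall from a starting rate: 100 * (start - end) / start.

    Negative when the rate rose; no clamping is applied.
    """
    if not rate_start > 0:
        raise ValueError(f"percent_decline requires a positive start, got {rate_start}")
    return 100.0 * (rate_start - rate_end) / rate_start


def mortality_rate(deaths: float, person_years: float) -> float:
    """Crude mortality rate per 100,000 person-years."""
    if not person_years > 0:
        raise ValueError("person_years must be positive")
    if deaths < 0:
        raise ValueError("deaths must be nonnegative")
    return 1e5 * deaths / person_years


def summarize(panel: pd.DataFrame, by: str = "state", arm: int = 0) -> pd.DataFrame:
    """Eight-statistic summary rows of one arm's rates, keyed by state or year.

    ``by`` is "state" (one row per subject over all years) or "year" (one
    row per year over all subjects).  Empty groups are omitted with a
    warning.  Quartiles are type-7 linear interpolation.
    """
    panel = validate_panel(panel)
    if by not in ("state", "year"):
        raise ValueError(f"by must be 'state' or 'year', got {by!r}")
    if by == "year" and "year" not in panel.columns:
        raise ValueError("panel has no 'year' column")
    key = "subject" if by == "state" else "year"
    sub = panel[panel["race"] == int(arm)]
    if len(sub) == 0:
        raise ValueError(f"panel has no rows for arm {arm}")
    rows = []
    for k, g in sub.groupby(key, sort=True):
        x = g["rate"].to_numpy(dtype=float)
        if len(x) == 0:  # pragma: no cover - groupby drops empty groups
            logger.warning("empty group %r omitted from summary", k)
            continue
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        rows.append(
            {
                by: k,
                "mean": mean,
                "sd": sd,
                "cv": cv(mean, sd) if mean > 0 else np.nan,
                "min": float(np.min(x)),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)


def rank_states(values: dict[str, float], highest_first: bool = True) -> pd.DataFrame:
    """Dense ranking of states by a metric, ties sharing a rank.

    Returns a DataFrame ordered by rank (highest value first by default);
    equal values receive the same rank and are ordered by state label.
    """
    if len(values) == 0:
        raise ValueError("no states to rank")
    items = sorted(
        values.items(), key=lambda kv: (-kv[1] if highest_first else kv[1], kv[0])
    )
    ranks, last_val, rank = [], None, 0
    for state, val in items:
        if last_val is None or val != last_val:
            rank += 1
            last_val = val
        ranks.append({"state": state, "value": val, "rank": rank})
    return pd.DataFrame(ranks)
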