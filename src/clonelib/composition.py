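"""Community composition tables from clone -> taxon assignments.

Aggregates per-clone taxon labels (phylum or class level, free strings)
into per-year and pooled count/percentage tables, plus integer two-group
ratios of the kind used for headline statements ("19 vs. 81%").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aggregate", "two_group_ratio"]


def _largest_remainder_pct(counts, decimals: int = 1) -> np.ndarray:
    """Percentages rounded to `decimals` so they sum to exactly 100.

    Shares are floored at the chosen granularity and the leftover units
    are assigned by decreasing fractional remainder (ties: larger count
    first, then input order), the largest-remainder apportionment rule.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    scale = 100 * 10**decimals
    exact = counts * scale / total
    floors = np.floor(exact).astype(np.int64)
    leftover = scale - floors.sum()
    order = sorted(
        range(len(counts)),
        key=lambda i: (-(exact[i] - floors[i]), -counts[i], i),
    )
    for i in order[:leftover]:
        floors[i] += 1
    return floors / 10**decimals

_COLUMNS = ["clone_id", "year", "domain", "taxon"]


def _as_frame(assignments) -> pd.DataFrame:
    if isinstance(assignments, pd.DataFrame):
        df = assignments.copy()
    else:
        df = pd.DataFrame(list(assignments), columns=_COLUMNS)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assignments missing columns {sorted(missing)}")
    if df["clone_id"].duplicated().any():
        dups = df.loc[df["clone_id"].duplicated(), "clone_id"].tolist()
        raise ValueError(f"duplicate clone assignments: {dups}")
    if (df["taxon"].astype(str).str.len() == 0).any():
        raise ValueError("empty taxon label")
    return df


def aggregate(assignments, pool: bool = False) -> pd.DataFrame:
    """Counts and percentages (1 dp) per taxon within each (year, domain).

    With `pool=True`, clone counts are summed across years per domain
    before percentages are computed, and the year column reads "pooled".
    Output order is deterministic: by year, domain, then decreasing count
    and taxon name, so the table is invariant to input order.
    """
    df = _as_frame(assignments)
    if df.empty:
        return pd.DataFrame(columns=["year", "domain", "taxon", "count", "percentage"])
    group_keys = ["domain"] if pool else ["year", "domain"]
    counts = (
        df.groupby(group_keys + ["taxon"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    counts["percentage"] = counts.groupby(group_keys)["count"].transform(
        _largest_remainder_pct
    )
    if pool:
        counts.insert(0, "year", "pooled")
    counts = counts.sort_values(
        ["year", "domain", "count", "taxon"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    return counts[["year", "domain", "taxon", "count", "percentage"]]


def two_group_ratio(count_a: int, count_b: int) -> tuple[int, int]:
    """Integer percentages for two groups, summing to exactly 100.

    Largest-remainder rounding: both shares are floored and the leftover
    percentage point(s) go to the larger fractional remainder (ties to
    the first group).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    total = count_a + count_b
    if total == 0:
        raise ValueError("both counts are zero")
    pa = 100.0 * count_a / total
    pb = 100.0 * count_b / total
    fa, fb = int(pa), int(pb)
    remaining = 100 - fa - fb
    if remaining:
        if (pa - fa) >= (pb - fb):
            fa += remaining
        else:
            fb += remaining
    return fa, fb
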