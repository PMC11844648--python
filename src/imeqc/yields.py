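"""Active electrode yield (AEY) and proportion z-tests.

AEY for a treatment group in a week is the number of active channels
(channels with at least one active single unit) divided by the group's
total analyzable channels: 16 channels per device x number of animals,
excluding channels that never have any active units over the whole study.
Phase proportions pool the weekly numerators and denominators across the
weeks of a phase (weeks 1-4 or 5-8). Group differences are assessed with
the two-sided pooled two-proportion z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["YieldResult", "make_activity_table", "collapse_sessions",
           "ever_active_channels", "weekly_aey", "phase_proportion",
           "two_proportion_ztest"]

ACTIVITY_COLUMNS = ["group", "animal", "week", "channel", "n_units"]


@dataclass
class YieldResult:
    group: str
    scope: str          # "week_<w>" or a phase label
    n_active: int
    n_total: int

    @property
    def proportion(self) -> float:
        return self.n_active / self.n_total


def make_activity_table(entries) -> pd.DataFrame:
    """Normalize raw activity entries into the canonical table.

    Accepts a DataFrame or an iterable of (group, animal, week, channel,
    n_units) rows; an optional ``session`` column is collapsed to the week
    level (a channel is active in a week iff it is active in >= 1 session
    of that week, so session counts sum).
    """
    if isinstance(entries, pd.DataFrame):
        df = entries.copy()
    else:
        df = pd.DataFrame(entries, columns=ACTIVITY_COLUMNS)
    missing = set(ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    if (df["n_units"] < 0).any():
        raise ValueError("unit counts must be >= 0")
    if "session" in df.columns:
        df = collapse_sessions(df)
    return df[ACTIVITY_COLUMNS].copy()


def collapse_sessions(df: pd.DataFrame) -> pd.DataFrame:
    """Sum per-session unit counts within each (group, animal, week,
    channel); biweekly recordings collapse to one weekly entry."""
    return (df.groupby(["group", "animal", "week", "channel"], as_index=False)
              ["n_units"].sum())


def ever_active_channels(table: pd.DataFrame) -> pd.DataFrame:
    """Channels with > 0 units in at least one week of the whole study,
    per (group, animal)."""
    tot = table.groupby(["group", "animal", "channel"])["n_units"].sum()
    keep = tot[tot > 0].reset_index()[["group", "animal", "channel"]]
    return keep


def weekly_aey(table: pd.DataFrame) -> list[YieldResult]:
    """Weekly AEY per group over ever-active channels.

    The denominator for (group, week) is the group's count of ever-active
    channels (summed over animals); the numerator is how many of those are
    active (count > 0) that week. The table must span the full study so
    the ever-active exclusion is well defined.
    """
    if table.empty:
        raise ValueError("empty activity table")
    table = make_activity_table(table)
    ever = ever_active_channels(table)
    ever_n = ever.groupby("group").size()
    sub = table.merge(ever, on=["group", "animal", "channel"])
    results = []
    for group in sorted(table["group"].unique()):
        if group not in ever_n.index:
            continue
        n_total = int(ever_n[group])
        g = sub[sub["group"] == group]
        for week in sorted(table["week"].unique()):
            gw = g[g["week"] == week]
            n_active = int((gw["n_units"] > 0).sum())
            results.append(YieldResult(group=group, scope=f"week_{week}",
                                       n_active=n_active, n_total=n_total))
    return results


def phase_proportion(table: pd.DataFrame, weeks) -> list[YieldResult]:
    """Pooled active-channel proportion over a set of weeks: numerators
    and denominators of the weekly AEY are summed across the phase."""
    weeks = sorted(set(int(w) for w in weeks))
    if not weeks:
        raise ValueError("empty week set")
    if any(w < 1 or w > 8 for w in weeks):
        raise ValueError("weeks must lie in 1-8")
    weekly = weekly_aey(table)
    label = f"W{weeks[0]}_{weeks[-1]}"
    results = []
    for group in sorted({r.group for r in weekly}):
        rs = [r for r in weekly if r.group == group
              and int(r.scope.split("_")[1]) in weeks]
        results.append(YieldResult(group=group, scope=label,
                                   n_active=sum(r.n_active for r in rs),
                                   n_total=sum(r.n_total for r in rs)))
    return results


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int
                         ) -> tuple[float, float]:
    """Two-sided pooled-variance two-proportion z-test.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion; P from the standard normal. Degenerate pooled proportions
    (0 or 1) give z = 0, P = 1 with a warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not (0 <= x <= n):
            raise ValueError("need 0 <= x <= n and n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        import warnings
        warnings.warn("pooled proportion degenerate; z undefined, set to 0")
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p
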