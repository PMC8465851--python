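"""Clinical cohort summaries and two-group comparisons.

Reproduces the descriptive statistics of the patient table (mean +/- sample
SD per subgroup and overall, reported as half-up-rounded integers) and the
exact Wilcoxon rank-sum comparisons between subgroups.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .discover import wilcoxon_ranksum

__all__ = ["round_half_up", "group_summary", "compare_groups"]

GROUP_COLUMN = "subgroup"


def round_half_up(x: float) -> int:
    """Integer rounding with .5 always going up (report convention)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _check(table: pd.DataFrame, variable: str) -> None:
    if variable not in table.columns:
        raise ValueError(f"unknown variable {variable!r}; columns: {list(table.columns)}")
    if GROUP_COLUMN not in table.columns:
        raise ValueError(f"cohort table needs a {GROUP_COLUMN!r} column")


def group_summary(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-group and overall mean +/- SD of one numeric variable.

    SD is the n-1 sample standard deviation.  Columns ``mean_int`` and
    ``sd_int`` carry the half-up integer rounding used in reports; the
    unrounded values are kept alongside.  Requires >= 2 patients per group.
    """
    _check(table, variable)
    rows = []
    groups = list(dict.fromkeys(table[GROUP_COLUMN]))  # stable order
    for name, sub in [(g, table[table[GROUP_COLUMN] == g]) for g in groups] + [("overall", table)]:
        values = sub[variable].to_numpy(dtype=float)
        if values.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 patients")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        rows.append((name, values.size, mean, sd, round_half_up(mean), round_half_up(sd)))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "mean_int", "sd_int"])


def compare_groups(table: pd.DataFrame, variable: str, group_a: str, group_b: str) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two subgroups."""
    _check(table, variable)
    a = table.loc[table[GROUP_COLUMN] == group_a, variable].to_numpy(dtype=float)
    b = table.loc[table[GROUP_COLUMN] == group_b, variable].to_numpy(dtype=float)
    for name, v in ((group_a, a), (group_b, b)):
        if v.size == 0:
            raise ValueError(f"group {name!r} absent from cohort table")
    return wilcoxon_ranksum(a, b)
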