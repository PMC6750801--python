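"""Cohort summary tables (one row per subject) in the clinical-paper style.

Percentages are 100 * count / non-missing group size, rounded half-up to
one decimal; missing values are excluded from the denominator of their
variable and reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANCESTRY_LEVELS = ("African", "European", "Hispanic", "NativeAmerican")
INCOME_LABELS = {0.0: "<US$20,000", 1.0: "US$20,000-59,999", 2.0: "US$60,000+"}


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (31.15 -> 31.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Per-group descriptive table plus missing-value counts.

    ``table`` rows carry ``variable`` plus, per outcome group G, ``G_count``
    and ``G_pct`` (or ``G_mean`` / ``G_sd`` for continuous variables).
    """

    table: pd.DataFrame
    group_sizes: dict
    missing: dict

    def formatted(self) -> pd.DataFrame:
        """Publication-style strings: "count (pct)" or "mean (sd)"."""
        out = {"variable": self.table["variable"]}
        for g in self.group_sizes:
            vals = []
            for _, row in self.table.iterrows():
                if not np.isnan(row.get(f"{g}_mean", np.nan)):
                    vals.append(f"{row[f'{g}_mean']} ({row[f'{g}_sd']})")
                else:
                    vals.append(f"{int(row[f'{g}_count'])} ({row[f'{g}_pct']})")
            out[g] = vals
        return pd.DataFrame(out)


def _count_pct(series: pd.Series, level) -> tuple[int, float]:
    valid = series.dropna()
    n = int((valid == level).sum())
    denom = len(valid)
    pct = round_half_up(100.0 * n / denom) if denom else float("nan")
    return n, pct


def summarize_cohort(records: pd.DataFrame, cohort=None) -> CohortSummary:
    """Descriptive cohort table: ancestry, income, delivery and history rates.

    ``records`` may hold several samples per subject; one row per subject is
    used.  Returns counts with percentages (one decimal, half-up) per
    outcome group, mean (SD) age, and per-variable missing counts.
    """
    subjects = records.drop_duplicates("subject_id")
    groups = {g: subjects[subjects["outcome"] == g] for g in ("PTB", "TB")}
    sizes = {g: len(df) for g, df in groups.items()}
    if min(sizes.values(), default=0) == 0:
        logger.warning("summarize_cohort: an outcome group is empty")

    missing = {
        g: {"income_bracket": int(df["income_bracket"].isna().sum())}
        for g, df in groups.items()
    }

    rows: list[dict] = []

    def add_categorical(label, column, level):
        entry = {"variable": label}
        for g, df in groups.items():
            if len(df):
                n, pct = _count_pct(df[column], level)
            else:
                n, pct = 0, float("nan")
            entry[f"{g}_count"] = n
            entry[f"{g}_pct"] = pct
        rows.append(entry)

    entry = {"variable": "Mean age (years)"}
    for g, df in groups.items():
        entry[f"{g}_mean"] = round_half_up(df["age"].mean()) if len(df) else np.nan
        entry[f"{g}_sd"] = (round_half_up(df["age"].std(ddof=1), 2)
                            if len(df) > 1 else np.nan)
    rows.append(entry)

    for level in ANCESTRY_LEVELS:
        add_categorical(f"Ancestry: {level}", "ancestry", level)
    for code, label in INCOME_LABELS.items():
        add_categorical(f"Income: {label}", "income_bracket", code)
    add_categorical("Vaginal delivery", "vaginal_delivery", 1)
    add_categorical("Previous preterm", "history_ptb", 1)
    add_categorical("PPROM", "pprom", 1)

    table = pd.DataFrame(rows)
    for g in groups:
        if f"{g}_mean" not in table:
            table[f"{g}_mean"] = np.nan
    return CohortSummary(table=table, group_sizes=sizes, missing=missing)
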