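"""Likert rating summaries and one-way ANOVA.

Ratings arrive as a long-form table with columns ``characteristic``,
``tool``, ``structure`` and ``rating`` (1 = very unsatisfied … 5 = very
satisfied). Summaries report the arithmetic mean and the sample
(n−1-denominator) standard deviation per (characteristic, tool) across
structures. Group differences are tested with the one-way ANOVA statistic

    F = (SSB / (k − 1)) / (SSW / (N − k))

where SSB is the between-group and SSW the within-group sum of squares;
the p-value is the upper tail of the F(k−1, N−k) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "AnovaResult",
    "load_ratings",
    "summarize_likert",
    "anova_oneway",
    "anova_by_characteristic",
    "round_half_up",
    "format_p",
]

REQUIRED_COLUMNS = ("characteristic", "tool", "structure", "rating")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero at the given decimal place (display rounding)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float, floor: float = 0.001) -> str:
    """Report tiny p-values as an inequality (e.g. '< 0.001')."""
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    ssb: float
    ssw: float
    p_value: float


def load_ratings(path) -> pd.DataFrame:
    """Read a delimited rating table (CSV/TSV inferred from content)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"rating table {path} lacks columns {missing}")
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    if ratings.isna().any():
        raise ValidationError(f"non-numeric ratings in {path}")
    if ((ratings < 1) | (ratings > 5)).any():
        raise ValidationError("ratings must lie in [1, 5]")
    df["rating"] = ratings.astype(float)
    return df


def summarize_likert(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mean ± sample SD of ratings per (characteristic, tool) across structures.

    Returns full-precision ``mean``/``sd`` columns plus half-up display
    roundings and a formatted "mean ± SD" string. Groups need at least two
    observations for the SD.
    """
    missing = [c for c in ("characteristic", "tool", "rating") if c not in table.columns]
    if missing:
        raise ValidationError(f"rating table lacks columns {missing}")
    if table.empty:
        raise ValidationError("empty rating table")
    rows = []
    for (char, tool), grp in table.groupby(["characteristic", "tool"], sort=False):
        vals = grp["rating"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValidationError(
                f"group ({char!r}, {tool!r}) has {len(vals)} observation(s); >= 2 required"
            )
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "characteristic": char,
                "tool": tool,
                "n": len(vals),
                "mean": mean,
                "sd": sd,
                "mean_display": round_half_up(mean, decimals),
                "sd_display": round_half_up(sd, decimals),
                "summary": f"{round_half_up(mean, decimals):.{decimals}f} ± "
                f"{round_half_up(sd, decimals):.{decimals}f}",
            }
        )
    return pd.DataFrame(rows)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across k groups.

    SSB = Σ n_g (ȳ_g − ȳ)², SSW = Σ_g Σ_i (y_gi − ȳ_g)²,
    F = (SSB/(k−1)) / (SSW/(N−k)), p from the F upper tail.
    """
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("every group needs at least 2 observations")
    n_total = sum(len(a) for a in arrays)
    if n_total <= k:
        raise ValidationError("total observations must exceed the number of groups")
    grand = float(np.concatenate(arrays).mean())
    ssb = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))
    df1 = k - 1
    df2 = n_total - k
    if ssw == 0:
        raise ValidationError("zero within-group variance; F undefined")
    f_stat = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return AnovaResult(F=f_stat, df1=df1, df2=df2, ssb=ssb, ssw=ssw, p_value=p)


def anova_by_characteristic(
    table: pd.DataFrame, characteristic: str
) -> AnovaResult:
    """One-way ANOVA of ratings across tools for one visual characteristic."""
    sub = table[table["characteristic"] == characteristic]
    if sub.empty:
        raise ValidationError(f"no rows for characteristic {characteristic!r}")
    groups = [g["rating"].to_numpy(dtype=float) for _, g in sub.groupby("tool", sort=False)]
    return anova_oneway(groups)
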