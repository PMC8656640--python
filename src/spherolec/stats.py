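"""Group statistics for volume tables: ANOVA, Tukey HSD, box-whisker.

The comparison recipe is the one standard in 3D-culture morphometry:
one-way fixed-effects ANOVA on a compartment's volumes across groups,
followed by Tukey's HSD post hoc test at family-wise α = 0.05, with
box-and-whisker summaries in which boxes are interquartile ranges and
whiskers are the minimum and maximum (not 1.5·IQR fences). Quartiles use
linear interpolation of order statistics (the default of
``numpy.percentile``). Replicates are treated as exchangeable
observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigurationError, UndefinedStatisticError

__all__ = [
    "AnovaResult",
    "TukeyComparison",
    "TukeyResult",
    "validate_volume_table",
    "one_way_anova",
    "tukey_hsd",
    "box_whisker_summary",
]


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int  # k - 1
    df_within: int  # N - k
    p_value: float
    group_means: dict


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(b) - mean(a)
    ci_low: float
    ci_high: float
    p_adj: float
    significant: bool  # p_adj <= alpha


@dataclass
class TukeyResult:
    comparisons: list[TukeyComparison]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def validate_volume_table(table: pd.DataFrame) -> None:
    """Check the long-format volume table contract."""
    required = {"condition", "day", "replicate", "compartment", "volume"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"volume table missing columns {sorted(missing)}")
    if (table["volume"] < 0).any():
        raise ConfigurationError("volume table contains negative volumes")
    keys = table[["condition", "day", "replicate", "compartment"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ConfigurationError(f"duplicate volume-table key {tuple(dup)}")


def _extract_groups(table: pd.DataFrame, response: str, group: str):
    if group not in table.columns or response not in table.columns:
        raise ConfigurationError(f"table lacks '{group}' or '{response}' column")
    grouped = {
        name: np.asarray(sub[response], dtype=float)
        for name, sub in table.groupby(group, sort=True)
    }
    if len(grouped) < 2:
        raise ConfigurationError(f"need >= 2 groups in '{group}', got {len(grouped)}")
    for name, vals in grouped.items():
        if len(vals) < 2:
            raise ConfigurationError(f"group '{name}' has {len(vals)} observation(s); need >= 2")
    pooled_ss = sum(((v - v.mean()) ** 2).sum() for v in grouped.values())
    if pooled_ss == 0:
        raise UndefinedStatisticError(
            "ANOVA undefined: zero within-group variance in every group"
        )
    return grouped


def one_way_anova(table: pd.DataFrame, response: str = "volume",
                  group: str = "condition") -> AnovaResult:
    """Classical fixed-effects one-way ANOVA on the selected response."""
    groups = _extract_groups(table, response, group)
    arrays = list(groups.values())
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    return AnovaResult(
        f_stat=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        group_means={name: float(a.mean()) for name, a in groups.items()},
    )


def tukey_hsd(table: pd.DataFrame, response: str = "volume", group: str = "condition",
              alpha: float = 0.05) -> TukeyResult:
    """All pairwise comparisons via the studentized-range distribution.

    ``significant`` is declared at ``p_adj <= alpha``, consistent with the
    confidence interval excluding zero.
    """
    groups = _extract_groups(table, response, group)  # validates preconditions
    endog = np.asarray(table[response], dtype=float)
    labels = np.asarray(table[group]).astype(str)
    res = pairwise_tukeyhsd(endog, labels, alpha=alpha)
    comparisons = []
    for (a, b), diff, (lo, hi), p in zip(
        ((res.groupsunique[i], res.groupsunique[j]) for i, j in zip(*np.triu_indices(len(res.groupsunique), 1))),
        res.meandiffs, res.confint, res.pvalues,
    ):
        comparisons.append(
            TukeyComparison(
                group_a=str(a),
                group_b=str(b),
                mean_diff=float(diff),
                ci_low=float(lo),
                ci_high=float(hi),
                p_adj=float(p),
                significant=bool(p <= alpha),
            )
        )
    del groups
    return TukeyResult(comparisons=comparisons, alpha=alpha)


def box_whisker_summary(table: pd.DataFrame, group: str = "condition",
                        response: str = "volume") -> pd.DataFrame:
    """Five-number summary per group: (min, q1, median, q3, max).

    Whiskers are the minimum and maximum observations; quartiles use
    linear interpolation of order statistics.
    """
    if group not in table.columns or response not in table.columns:
        raise ConfigurationError(f"table lacks '{group}' or '{response}' column")
    if table.empty:
        raise ConfigurationError("empty table")
    rows = []
    for name, sub in table.groupby(group, sort=True):
        v = np.asarray(sub[response], dtype=float)
        if v.size == 0:
            raise ConfigurationError(f"empty group '{name}'")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append({group: name, "min": v.min(), "q1": q1, "median": med,
                     "q3": q3, "max": v.max()})
    return pd.DataFrame(rows)
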