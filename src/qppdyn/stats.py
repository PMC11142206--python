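"""Group statistics on per-scan metrics.

The central tool is an unbalanced two-way ANOVA with interaction
(virus × stimulation level), using Type III sums of squares with
sum-to-zero factor coding by default (Type II available). Repeated scans
from one animal are treated as independent units. Post-hoc pairwise
comparisons use Tukey's HSD (studentized-range adjusted p values).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    flag: str | None = None  # e.g. 'zero-residual'


@dataclass
class AnovaTable:
    """F, degrees of freedom and p for both main effects and the interaction."""

    effects: dict[str, AnovaEffect]
    cell_counts: dict[tuple[str, str], int]
    ss_type: str
    n_used: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "effect": name, "F": e.F, "df1": e.df1, "df2": e.df2,
                "p": e.p, "flag": e.flag or "",
            }
            for name, e in self.effects.items()
        ]
        return pd.DataFrame(rows)


_ZERO_RESID_RTOL = 1e-10


def two_way_anova(
    values,
    virus,
    stimulation,
    ss_type: str = "III",
) -> AnovaTable:
    """Unbalanced two-way ANOVA with interaction on per-scan values.

    Undefined (NaN) values are dropped with a logged count; every cell of
    the observed design must remain nonempty. With zero residual variance
    the F statistics are reported as flagged sentinels (0 for a zero
    effect sum of squares, +inf otherwise) rather than silently.
    """
    if ss_type not in ("II", "III"):
        raise InvalidConfigError("ss_type must be 'II' or 'III'")
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "virus": list(virus),
            "stim": list(stimulation),
        }
    )
    n0 = len(df)
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("two_way_anova: dropped %d undefined value(s)", n_dropped)

    v_levels = sorted(df["virus"].unique())
    s_levels = sorted(df["stim"].unique())
    if len(v_levels) < 2 or len(s_levels) < 2:
        raise InvalidConfigError("need >= 2 levels per factor")
    counts = {}
    for v in v_levels:
        for s in s_levels:
            n = int(((df["virus"] == v) & (df["stim"] == s)).sum())
            if n == 0:
                raise InvalidConfigError(f"empty design cell ({v}, {s})")
            counts[(v, s)] = n

    model = smf.ols("value ~ C(virus, Sum) * C(stim, Sum)", data=df).fit()
    typ = 3 if ss_type == "III" else 2
    tab = sm.stats.anova_lm(model, typ=typ)

    name_map = {
        "C(virus, Sum)": "virus",
        "C(stim, Sum)": "stimulation",
        "C(virus, Sum):C(stim, Sum)": "interaction",
    }
    ss_resid = float(tab.loc["Residual", "sum_sq"])
    df_resid = int(tab.loc["Residual", "df"])
    ss_total = float(np.sum((df["value"] - df["value"].mean()) ** 2))
    zero_resid = ss_resid <= _ZERO_RESID_RTOL * max(ss_total, 1e-300)

    effects: dict[str, AnovaEffect] = {}
    for row, name in name_map.items():
        ss = float(tab.loc[row, "sum_sq"])
        df1 = int(tab.loc[row, "df"])
        if zero_resid:
            big = ss > _ZERO_RESID_RTOL * max(ss_total, 1e-300)
            F = np.inf if big else 0.0
            p = 0.0 if big else 1.0
            effects[name] = AnovaEffect(F, df1, df_resid, p, flag="zero-residual")
            continue
        F = (ss / df1) / (ss_resid / df_resid)
        p = float(spstats.f.sf(F, df1, df_resid))
        effects[name] = AnovaEffect(float(F), df1, df_resid, p)
    if zero_resid:
        warnings.warn("zero residual variance: ANOVA F values are sentinels")
    return AnovaTable(
        effects=effects, cell_counts=counts, ss_type=ss_type,
        n_used=len(df), n_dropped=n_dropped,
    )


def tukey_hsd(values, group_labels) -> pd.DataFrame:
    """All pairwise mean differences with studentized-range adjusted p.

    Returns a table with columns group1, group2, diff (mean1 − mean2),
    p_adj, flag. Groups with fewer than 2 values are an error. With zero
    pooled within-group variance the p values are boundary sentinels
    (1 for a zero difference, 0 otherwise), flagged.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(group_labels)})
    df = df.dropna(subset=["value"])
    levels = sorted(df["group"].unique())
    if len(levels) < 2:
        raise InvalidConfigError("need >= 2 groups")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in levels]
    for g, s in zip(levels, samples):
        if s.size < 2:
            raise InvalidConfigError(f"group {g!r} has < 2 values")

    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / sum(
        s.size - 1 for s in samples
    )
    scale = max(float(np.abs(df["value"]).max()), 1e-300)
    rows = []
    if mse <= 1e-20 * scale**2:
        warnings.warn("zero within-group variance: Tukey p values are sentinels")
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                diff = float(samples[i].mean() - samples[j].mean())
                rows.append(
                    {"group1": levels[i], "group2": levels[j], "diff": diff,
                     "p_adj": 1.0 if diff == 0 else 0.0, "flag": "zero-variance"}
                )
        return pd.DataFrame(rows)

    res = spstats.tukey_hsd(*samples)
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group1": levels[i],
                    "group2": levels[j],
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(res.pvalue[i, j]),
                    "flag": "",
                }
            )
    return pd.DataFrame(rows)
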