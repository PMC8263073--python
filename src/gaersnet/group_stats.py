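"""Group-level statistics beyond NBS.

Mann-Whitney comparison of edge-weight (Fisher-z) distributions between
group connectomes, two-factor fixed-effects ANOVA (group x brain region,
with interaction) on local node parameters, and per-region post-hoc
unpaired t-tests.  ANOVA uses Type-II sums of squares, appropriate for the
unbalanced group sizes typical of animal studies; post-hoc p-values are
reported uncorrected (the study convention) with a BH-adjusted column
always emitted alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .connectivity import ConnectivityMatrix

__all__ = [
    "MannWhitneyEdges",
    "compare_z_distributions",
    "local_param_table",
    "anova_local_params",
    "posthoc_ttests",
]

LOCAL_PARAM_COLUMNS = ("subject", "group", "region", "metric", "value")


@dataclass(frozen=True)
class MannWhitneyEdges:
    """Rank-sum comparison of two sets of nonzero edge z-values."""

    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float

    @property
    def direction(self) -> str:
        if self.median_b > self.median_a:
            return "B>A"
        if self.median_a > self.median_b:
            return "A>B"
        return "A=B"


def compare_z_distributions(
    matA: ConnectivityMatrix, matB: ConnectivityMatrix
) -> MannWhitneyEdges:
    """Two-sided Mann-Whitney U on nonzero edge z-values of two matrices.

    The samples are the nonzero unique off-diagonal entries of each
    (group-average) matrix in the Fisher-z domain; both edge counts and the
    direction of the median shift are reported.
    """
    a = matA.to_z().edge_values(nonzero=True)
    b = matB.to_z().edge_values(nonzero=True)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 nonzero edges per matrix")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return MannWhitneyEdges(
        u_statistic=float(u),
        p_value=float(p),
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def local_param_table(records: Sequence[dict] | pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format local-parameter table.

    Columns: subject, group, region, metric, value; one value per
    (subject, region, metric).
    """
    df = pd.DataFrame(records)
    missing = set(LOCAL_PARAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject", "region", "metric"])
    if dup.any():
        raise ValueError("duplicate (subject, region, metric) rows")
    return df.loc[:, list(LOCAL_PARAM_COLUMNS)].copy()


def anova_local_params(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Two-factor fixed-effects ANOVA with interaction on a node metric.

    Factors are group and brain region; Type-II sums of squares (robust to
    the unbalanced subject counts per group).  Returns a table with rows
    group / region / interaction / residual and columns sum_sq, df, F, p.
    For R regions the region df is R - 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[table["metric"] == metric].copy()
    if df.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    groups = df["group"].unique()
    regions = df["region"].unique()
    if len(groups) < 2 or len(regions) < 2:
        raise ValueError("need at least 2 groups and 2 regions")
    counts = df.groupby(["group", "region"], sort=True).size()
    full = pd.MultiIndex.from_product([sorted(groups), sorted(regions)])
    empty = [idx for idx in full if counts.get(idx, 0) == 0]
    if empty:
        raise ValueError(f"empty design cells: {empty[:10]}")
    model = smf.ols("value ~ C(group) * C(region)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(group)": "group",
        "C(region)": "region",
        "C(group):C(region)": "interaction",
        "Residual": "residual",
    }
    aov = aov.rename(index=rename)
    aov.index.name = "factor"
    return aov.rename(columns={"PR(>F)": "p"})


def posthoc_ttests(
    table: pd.DataFrame, metric: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-region unpaired two-sided t-tests between two groups.

    Returns one row per testable region with t, uncorrected p (study
    convention) and a BH-adjusted p column; regions with fewer than 2
    subjects in either group are skipped and flagged in ``attrs``.
    """
    df = table[table["metric"] == metric]
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError("post-hoc t-tests require exactly 2 groups")
    ga, gb = groups
    rows = []
    skipped = []
    for region, sub in df.groupby("region", sort=True):
        a = sub.loc[sub["group"] == ga, "value"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == gb, "value"].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            skipped.append(region)
            continue
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "region": region,
                "t": float(t),
                "p": float(p),
                "n_a": int(a.size),
                "n_b": int(b.size),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
        out["significant_uncorrected"] = out["p"] < alpha
    out.attrs["skipped_regions"] = skipped
    out.attrs["groups"] = (ga, gb)
    return out
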