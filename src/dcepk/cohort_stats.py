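"""Cohort-level test-retest statistics.

Reduces paired parameter maps to one summary per animal (over the order-3
mask, where all three parameters are identifiable), forms test-retest
differences, and runs the study's statistics: a paired t-test within each
treatment-time group, a one-way ANOVA across groups, and the planned
contrast pooling the early (2 & 4 h) against the late (12 & 24 h) groups
using the ANOVA pooled error.

Differences are computed in two modes: absolute (retest - test, the units
of the parameter itself) and percent (100 x (retest - test)/test). Group
summary tables of the published kind are in absolute mode; boxplot-style
distribution summaries use percent mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyPair",
    "summarize_roi",
    "build_cohort_table",
    "paired_t_per_group",
    "anova_with_contrast",
    "export_boxplot_data",
    "group_difference_summary",
    "PARAMS",
]

PARAMS = ("vp", "ktrans", "ve")
EARLY_GROUPS = (2, 4)
LATE_GROUPS = (12, 24)


@dataclass
class StudyPair:
    """Masked parameter maps of both sessions of one animal.

    ``roi`` optionally restricts all summaries to an analysis region (the
    tumor as drawn on the localization images); without it the whole-volume
    order-3 mask is used.
    """

    animal_id: str
    group_h: int
    test_maps: dict[str, np.ndarray]    # output of make_masked_maps
    retest_maps: dict[str, np.ndarray]
    roi: np.ndarray | None = None

    def mask(self, rule: str) -> np.ndarray:
        m_test = self.test_maps["model3_mask"]
        m_retest = self.retest_maps["model3_mask"]
        if rule == "test":
            m = m_test
        elif rule == "retest":
            m = m_retest
        elif rule == "intersection":
            m = m_test & m_retest
        else:
            raise ValueError(f"unknown mask rule {rule!r}")
        return m & self.roi if self.roi is not None else m


def summarize_roi(
    pair: StudyPair,
    statistic: str = "mean",
    mask_rule: str = "intersection",
) -> dict:
    """One cohort-table row: per-parameter summaries and differences.

    Returns a dict with ``excluded=True`` and a reason instead of numbers
    when the order-3 mask is empty under the requested rule.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    reduce = np.nanmean if statistic == "mean" else np.nanmedian
    mask = pair.mask(mask_rule)
    row: dict = {"animal_id": pair.animal_id, "group_h": pair.group_h,
                 "n_voxels": int(mask.sum()), "excluded": False, "reason": ""}
    if not mask.any():
        row.update(excluded=True, reason="no order-3 voxels under mask rule")
        return row
    for p in PARAMS:
        t = float(reduce(pair.test_maps[p][mask]))
        r = float(reduce(pair.retest_maps[p][mask]))
        d = r - t
        row[f"{p}_test"] = t
        row[f"{p}_retest"] = r
        row[f"{p}_dif"] = d
        row[f"{p}_dif_pct"] = 100.0 * d / t if t != 0 else np.nan
        row[f"{p}_pct_flag"] = t == 0
    return row


def build_cohort_table(
    pairs: list[StudyPair],
    statistic: str = "mean",
    mask_rule: str = "intersection",
) -> pd.DataFrame:
    """Assemble the per-animal cohort table (excluded rows kept, flagged)."""
    rows = [summarize_roi(p, statistic, mask_rule) for p in pairs]
    return pd.DataFrame(rows)


def _included(table: pd.DataFrame) -> pd.DataFrame:
    return table[~table["excluded"].astype(bool)]


def _dif_col(param: str, mode: str) -> str:
    if mode == "absolute":
        return f"{param}_dif"
    if mode == "percent":
        return f"{param}_dif_pct"
    raise ValueError("mode must be 'absolute' or 'percent'")


def paired_t_per_group(table: pd.DataFrame, param: str, mode: str = "absolute") -> pd.DataFrame:
    """Two-sided paired t-test of retest vs test within each time group.

    Zero-variance difference sets (t undefined) are flagged rather than
    reported with a spurious p-value.
    """
    col = _dif_col(param, mode)
    out = []
    for group_h, sub in _included(table).groupby("group_h"):
        d = sub[col].to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        n = d.size
        rec = {"group_h": group_h, "n": n, "mean_dif": d.mean() if n else np.nan,
               "sd_dif": d.std(ddof=1) if n > 1 else np.nan,
               "t": np.nan, "df": n - 1, "p": np.nan, "zero_variance": False}
        if n >= 2:
            if np.allclose(d, d[0]):
                rec["zero_variance"] = True
            else:
                # paired t on (retest, test) == one-sample t on the differences
                t, p = stats.ttest_1samp(d, 0.0)
                rec["t"], rec["p"] = float(t), float(p)
        out.append(rec)
    return pd.DataFrame(out).sort_values("group_h").reset_index(drop=True)


@dataclass
class ContrastResult:
    """One-way ANOVA with a planned pooled-group contrast."""

    f_overall: float
    p_overall: float
    df_between: int
    df_within: int
    mse: float
    ss_total: float
    ss_between: float
    ss_within: float
    estimate: float
    se: float
    t: float
    p: float
    group_means: dict[int, float] = field(default_factory=dict)
    group_ns: dict[int, int] = field(default_factory=dict)


def anova_with_contrast(
    table: pd.DataFrame,
    param: str,
    mode: str = "absolute",
    plus_groups: tuple[int, ...] = EARLY_GROUPS,
    minus_groups: tuple[int, ...] = LATE_GROUPS,
) -> ContrastResult:
    """One-way ANOVA over the time groups plus the planned pooled contrast.

    The contrast estimate is the pooled mean of the ``plus`` animals minus
    the pooled mean of the ``minus`` animals (size-weighted group means, so
    it equals the difference of the two published pooled-group means); its
    standard error uses the ANOVA pooled MSE with N - k degrees of freedom,
    and the p-value is the two-sided t probability.
    """
    col = _dif_col(param, mode)
    tab = _included(table)
    groups = {int(g): sub[col].dropna().to_numpy(dtype=float)
              for g, sub in tab.groupby("group_h")}
    groups = {g: v for g, v in groups.items() if v.size > 0}
    for g in (*plus_groups, *minus_groups):
        if g not in groups:
            raise ValueError(f"contrast group {g} h missing from the table")
    if len(groups) < 2 or any(v.size < 2 for v in groups.values()):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2")

    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total, k = all_vals.size, len(groups)
    ss_total = float(((all_vals - grand) ** 2).sum())
    ss_between = float(sum(v.size * (v.mean() - grand) ** 2 for v in groups.values()))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in groups.values()))
    df_b, df_w = k - 1, n_total - k
    mse = ss_within / df_w
    f_overall = (ss_between / df_b) / mse if mse > 0 else np.inf
    p_overall = float(stats.f.sf(f_overall, df_b, df_w)) if np.isfinite(f_overall) else 0.0

    # size-weighted coefficients reproduce pooled means of each side
    n_plus = sum(groups[g].size for g in plus_groups)
    n_minus = sum(groups[g].size for g in minus_groups)
    coef = {g: 0.0 for g in groups}
    for g in plus_groups:
        coef[g] = groups[g].size / n_plus
    for g in minus_groups:
        coef[g] = -groups[g].size / n_minus
    if abs(sum(coef.values())) > 1e-12:
        raise ValueError("contrast coefficients must sum to zero")
    estimate = float(sum(c * groups[g].mean() for g, c in coef.items()))
    se = float(np.sqrt(mse * sum(c**2 / groups[g].size for g, c in coef.items())))
    t = estimate / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df_w)) if np.isfinite(t) else 0.0
    return ContrastResult(
        f_overall=float(f_overall), p_overall=p_overall,
        df_between=df_b, df_within=df_w, mse=float(mse),
        ss_total=ss_total, ss_between=ss_between, ss_within=ss_within,
        estimate=estimate, se=se, t=float(t), p=p,
        group_means={g: float(v.mean()) for g, v in groups.items()},
        group_ns={g: int(v.size) for g, v in groups.items()},
    )


def group_difference_summary(
    table: pd.DataFrame,
    param: str,
    mode: str = "absolute",
    pools: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Pooled-group mean/SD of the differences (the published-table shape)."""
    pools = pools or {"2 and 4 hour": EARLY_GROUPS, "12 and 24 hour": LATE_GROUPS}
    col = _dif_col(param, mode)
    tab = _included(table)
    rows = []
    for label, gs in pools.items():
        d = tab[tab["group_h"].isin(gs)][col].dropna().to_numpy(dtype=float)
        rows.append({"pool": label, "n": d.size,
                     "mean": d.mean() if d.size else np.nan,
                     "sd": d.std(ddof=1) if d.size > 1 else np.nan})
    return pd.DataFrame(rows)


def export_boxplot_data(table: pd.DataFrame, param: str, mode: str = "percent") -> pd.DataFrame:
    """Per-group distribution summary for boxplot-style figures.

    Returns one row per group with median, quartiles, 1.5 x IQR whiskers
    and the list of outlying animal values (machine-readable).
    """
    col = _dif_col(param, mode)
    tab = _included(table)
    if tab.empty:
        raise ValueError("cohort table has no included rows")
    rows = []
    for group_h, sub in tab.groupby("group_h"):
        d = np.sort(sub[col].dropna().to_numpy(dtype=float))
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        in_lo, in_hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = d[(d >= in_lo) & (d <= in_hi)]
        rows.append({
            "group_h": int(group_h), "n": d.size,
            "median": med, "q1": q1, "q3": q3,
            "whisker_lo": inliers.min(), "whisker_hi": inliers.max(),
            "outliers": ";".join(f"{v:.6g}" for v in d[(d < in_lo) | (d > in_hi)]),
        })
    return pd.DataFrame(rows).sort_values("group_h").reset_index(drop=True)
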