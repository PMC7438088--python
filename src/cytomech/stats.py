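"""Group-level statistics and the cross-scale scaling regression.

Distribution-level comparisons (imaging-flow-cytometry features) use
two-sample Kolmogorov–Smirnov tests; biophysical properties use two-tailed
t tests for two groups and one-way ANOVA followed by Fisher's least
significant difference (LSD) post hoc test for multi-group designs, with
no family-wise correction beyond LSD.  Cross-system measurements are
harmonized by a multiplicative control-based normalization factor.  The
scaling analysis regresses one metric's group means on another's
(ordinary least squares on group means, not per-cell values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "RegressionResult",
    "summarize_groups",
    "compare_distributions_ks",
    "compare_groups",
    "fisher_lsd",
    "cross_system_scaling",
    "apply_scaling",
    "scaling_relationship",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    metric: str
    n: int
    mean: float
    sd: float
    control_normalized_mean: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int


def summarize_groups(
    table: pd.DataFrame,
    control_group: str | None = None,
) -> list[GroupSummary]:
    """Per-(group, metric) n/mean/SD from a tidy (group, metric, value) table."""
    summaries = []
    for metric, sub in table.groupby("metric", sort=False):
        control_mean = None
        if control_group is not None:
            ctrl = sub.loc[sub["group"] == control_group, "value"]
            control_mean = float(ctrl.mean()) if len(ctrl) else None
        for group, vals in sub.groupby("group", sort=False):
            v = vals["value"].to_numpy(dtype=float)
            summaries.append(
                GroupSummary(
                    group=str(group),
                    metric=str(metric),
                    n=len(v),
                    mean=float(v.mean()),
                    sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    control_normalized_mean=(
                        float(v.mean() / control_mean)
                        if control_mean not in (None, 0.0)
                        else None
                    ),
                )
            )
    return summaries


def compare_distributions_ks(sample_a: np.ndarray, sample_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def fisher_lsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons after a one-way ANOVA.

    Uses the pooled within-group mean square with N − k degrees of
    freedom; p-values are two-tailed and uncorrected (the LSD procedure).
    """
    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    n_tot = sum(len(a) for a in arrs)
    k = len(arrs)
    df_within = n_tot - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            se = np.sqrt(mse * (1.0 / len(a) + 1.0 / len(b)))
            t = (a.mean() - b.mean()) / se
            p = 2.0 * sps.t.sf(abs(t), df_within)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": a.mean() - b.mean(),
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    table: pd.DataFrame,
    design: str = "auto",
    equal_var: bool = True,
) -> dict:
    """Hypothesis tests on a tidy (group, value) table for one metric.

    Two groups → two-tailed t test (Student's by default, Welch with
    ``equal_var=False``).  More → one-way ANOVA plus Fisher LSD pairwise
    table.  ``design`` may force 'two-group' or 'multi-group'.
    """
    groups = {
        str(g): sub["value"].to_numpy(dtype=float)
        for g, sub in table.groupby("group", sort=False)
    }
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group '{g}' has fewer than two observations")
    if design == "auto":
        design = "two-group" if len(groups) == 2 else "multi-group"
    if design == "two-group":
        if len(groups) != 2:
            raise ValueError("two-group design requires exactly two groups")
        a, b = groups.values()
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        return {"design": "two-group", "t": float(t), "p": float(p)}
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    f, p = sps.f_oneway(*groups.values())
    return {
        "design": "multi-group",
        "F": float(f),
        "p": float(p),
        "lsd": fisher_lsd(groups),
    }


def cross_system_scaling(reference_control_mean: float, other_control_mean: float) -> float:
    """Normalization factor mapping another system onto the reference one.

    Both systems measure the same untreated control; the ratio of control
    means rescales the other system's measurements multiplicatively.
    """
    if reference_control_mean <= 0 or other_control_mean <= 0:
        raise ValueError("control means must be positive")
    return reference_control_mean / other_control_mean


def apply_scaling(values: np.ndarray, factor: float) -> np.ndarray:
    return np.asarray(values, dtype=float) * factor


def scaling_relationship(x_means: np.ndarray, y_means: np.ndarray) -> RegressionResult:
    """OLS regression of group means of one metric on another's.

    Operates on group means (one point per treatment group), mirroring the
    cross-scale analysis relating circularity, contractility, and
    hydraulic permeability.
    """
    x = np.asarray(x_means, dtype=float)
    y = np.asarray(y_means, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need at least three groups for a scaling regression")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_points=len(x),
    )
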