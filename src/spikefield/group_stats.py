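"""Group-comparison layer: normality check, one-way ANOVA with Tukey HSD.

The unit of analysis is the neuron: each neuron contributes one value per
(measure, band, state) — the mean over its six analysis segments.  Three
experimental groups (control / lesioned / L-DOPA) are compared per band with
a one-way ANOVA followed by Tukey's post-hoc pairwise comparisons
(Tukey-Kramer for unequal group sizes); two groups route to a two-tailed
unpaired t-test.  A Kolmogorov-Smirnov normality check is reported per
group, advisory only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["GroupComparison", "normality_check", "compare_groups"]


@dataclass
class GroupComparison:
    """One omnibus comparison across groups for one measure/band/state."""

    measure: str
    band: str
    unit_type: str
    state: str
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    test: str = "anova"

    def format_f(self) -> str:
        """Conventional report string, e.g. ``F (2,117) = 5.011, p = 0.0082``."""
        return (
            f"F ({self.df[0]},{self.df[1]}) = {self.f_statistic:.3f}, "
            f"p = {self.p_value:.4f}"
        )


def normality_check(groups: dict[str, np.ndarray]) -> dict[str, float]:
    """Kolmogorov-Smirnov p-value per group against a normal with the
    sample's moments.  Groups with < 5 values or zero spread get NaN
    (flagged, not fatal) — the check is advisory."""
    out: dict[str, float] = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 5 or v.std(ddof=1) == 0:
            out[name] = float("nan")
            continue
        out[name] = float(
            stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue
        )
    return out


def compare_groups(
    table: pd.DataFrame,
    measure: str,
    band: str,
    unit_type: str = "",
    state: str = "",
    value_column: str = "value",
    group_column: str = "group",
    alpha: float = 0.05,
) -> GroupComparison | None:
    """Omnibus comparison of ``value_column`` across groups.

    ``table`` holds one row per neuron (the 6-segment mean).  Rows may be
    pre-filtered or carry ``measure``/``band``/``unit_type``/``state``
    columns, which are used to subset when present.  Non-finite values are
    dropped (gated-out neurons).  With three or more groups: one-way ANOVA
    (df = (k-1, N-k)) plus Tukey HSD pairwise p-values; with exactly two:
    a two-tailed unpaired t-test.  Returns None when fewer than two groups
    have at least two values (skipped comparison).
    """
    sub = table
    for column, wanted in (
        ("measure", measure),
        ("band", band),
        ("unit_type", unit_type),
        ("state", state),
    ):
        if wanted and column in sub.columns:
            sub = sub[sub[column] == wanted]
    sub = sub[np.isfinite(sub[value_column].to_numpy(dtype=float))]
    grouped = {
        name: g[value_column].to_numpy(dtype=float)
        for name, g in sub.groupby(group_column)
    }
    grouped = {name: v for name, v in grouped.items() if v.size >= 2}
    if len(grouped) < 2:
        return None
    names = sorted(grouped)
    values = [grouped[n] for n in names]
    n_total = sum(v.size for v in values)
    k = len(values)
    means = {n: float(v.mean()) for n, v in zip(names, values)}
    sems = {n: float(stats.sem(v)) for n, v in zip(names, values)}
    ns = {n: int(v.size) for n, v in zip(names, values)}

    if k == 2:
        t_res = stats.ttest_ind(values[0], values[1])
        return GroupComparison(
            measure=measure,
            band=band,
            unit_type=unit_type,
            state=state,
            group_means=means,
            group_sems=sems,
            group_ns=ns,
            f_statistic=float(t_res.statistic**2),
            df=(1, n_total - 2),
            p_value=float(t_res.pvalue),
            pairwise_p={(names[0], names[1]): float(t_res.pvalue)},
            test="t-test",
        )

    f_stat, p_val = stats.f_oneway(*values)
    flat = np.concatenate(values)
    labels = np.concatenate([[n] * v.size for n, v in zip(names, values)])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    pairwise: dict[tuple[str, str], float] = {}
    for row in tukey.summary().data[1:]:
        pairwise[(str(row[0]), str(row[1]))] = float(row[3])
    return GroupComparison(
        measure=measure,
        band=band,
        unit_type=unit_type,
        state=state,
        group_means=means,
        group_sems=sems,
        group_ns=ns,
        f_statistic=float(f_stat),
        df=(k - 1, n_total - k),
        p_value=float(p_val),
        pairwise_p=pairwise,
        test="anova",
    )
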