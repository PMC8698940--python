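"""Group comparisons of morphometry read-outs.

Mirrors the statistical treatment standard for organ-culture morphometry:
values reported as mean +/- SEM; two groups compared by Student's t-test
(paired when the design pairs contralateral lobes from one animal,
otherwise two-sample with pooled variance); three or more groups by
one-way ANOVA with Bonferroni-adjusted pairwise post hoc tests against the
control group.  The multiple-testing family is the time grid within one
metric, since significance is reported per time point ("significant from
40 h onward").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupDesign", "compare_two", "compare_multi", "summarize"]


@dataclass
class GroupDesign:
    """Named groups of sample ids, optional contralateral pairing.

    ``pairing`` maps sample ids of the first group to their contralateral
    partners in the second group; it must be a bijection.  ``metric`` is a
    column of the morphometry table; ``times`` the sampled time grid.
    """

    groups: dict[str, list]
    metric: str = "total_tips"
    times: tuple = ()
    pairing: dict | None = None
    control: str | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for name, ids in self.groups.items():
            if len(ids) < 2:
                raise ValueError(f"group {name!r} has fewer than 2 samples")
        if self.pairing is not None:
            if len(self.groups) != 2:
                raise ValueError("pairing requires exactly two groups")
            a, b = self.groups.values()
            if sorted(self.pairing) != sorted(a) or sorted(
                self.pairing.values()
            ) != sorted(b):
                raise ValueError("pairing must be a bijection between the groups")
        if self.control is None:
            self.control = next(iter(self.groups))


#: metrics constant across the generation rows of one time point (taken
#: once per sample); anything else is summed over generations.
PER_TIME_METRICS = frozenset({"total_tips", "max_generation"})


def _values(table: pd.DataFrame, design: GroupDesign, group: str, time) -> pd.Series:
    sub = table[(table["time_h"] == time) & table["sample_id"].isin(design.groups[group])]
    grouped = sub.groupby("sample_id")[design.metric]
    return grouped.first() if design.metric in PER_TIME_METRICS else grouped.sum()


def summarize(table: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Long-format mean +/- SEM per (group, time); single-sample groups are
    flagged with an undefined SEM."""
    rows = []
    for g in design.groups:
        for t in design.times:
            v = _values(table, design, g, t)
            rows.append(
                dict(
                    group=g,
                    time_h=t,
                    metric=design.metric,
                    n=len(v),
                    mean=v.mean(),
                    sem=v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
                    sem_undefined=len(v) < 2,
                )
            )
    return pd.DataFrame(rows)


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def compare_two(table: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Two-group comparison per time point.

    Paired t-test when a pairing is declared, else pooled-variance
    two-sample t-test.  Bonferroni adjustment over the time grid.  Exact
    ties (zero variance of the differences / both groups constant and
    equal) are flagged and given statistic 0, p 1.
    """
    names = list(design.groups)
    if len(names) != 2:
        raise ValueError("compare_two needs exactly two groups")
    m = len(design.times)
    rows = []
    for t in design.times:
        va = _values(table, design, names[0], t)
        vb = _values(table, design, names[1], t)
        if design.pairing is not None:
            a = va.loc[list(design.pairing)].to_numpy(dtype=float)
            b = vb.loc[[design.pairing[k] for k in design.pairing]].to_numpy(dtype=float)
            test = "paired t"
            diffs = a - b
            tie = np.allclose(diffs.std(ddof=1), 0) and np.allclose(diffs.mean(), 0)
            if tie:
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_rel(a, b)
        else:
            a, b = va.to_numpy(dtype=float), vb.to_numpy(dtype=float)
            test = "two-sample t (pooled)"
            tie = np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0) \
                and np.allclose(a.mean(), b.mean())
            if tie:
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(a, b, equal_var=True)
        rows.append(
            dict(
                metric=design.metric,
                time_h=t,
                group_a=names[0],
                group_b=names[1],
                mean_a=a.mean(),
                mean_b=b.mean(),
                sem_a=a.std(ddof=1) / np.sqrt(len(a)),
                sem_b=b.std(ddof=1) / np.sqrt(len(b)),
                n_a=len(a),
                n_b=len(b),
                statistic=float(stat),
                p_raw=float(p),
                p_adj=_bonferroni(float(p), m),
                test=test,
                tie=bool(tie),
            )
        )
    return pd.DataFrame(rows)


def compare_multi(table: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """One-way ANOVA per time point plus Bonferroni pairwise post hoc
    against the control group."""
    names = list(design.groups)
    if len(names) < 3:
        raise ValueError("compare_multi needs at least three groups")
    others = [g for g in names if g != design.control]
    m = len(design.times) * len(others)
    rows = []
    for t in design.times:
        samples = {g: _values(table, design, g, t).to_numpy(dtype=float) for g in names}
        if any(len(v) == 0 for v in samples.values()):
            raise ValueError(f"empty group at time {t}")
        if all(np.allclose(v.std(ddof=1), 0) for v in samples.values()) and len(
            {v.mean() for v in samples.values()}
        ) == 1:
            f_stat, f_p = 0.0, 1.0
        else:
            f_stat, f_p = sps.f_oneway(*samples.values())
        ctrl = samples[design.control]
        for g in others:
            v = samples[g]
            tie = np.allclose(v.std(ddof=1), 0) and np.allclose(
                ctrl.std(ddof=1), 0
            ) and np.allclose(v.mean(), ctrl.mean())
            if tie:
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(ctrl, v, equal_var=True)
            rows.append(
                dict(
                    metric=design.metric,
                    time_h=t,
                    anova_F=float(f_stat),
                    anova_p=float(f_p),
                    control=design.control,
                    group=g,
                    mean_control=ctrl.mean(),
                    mean_group=v.mean(),
                    sem_group=v.std(ddof=1) / np.sqrt(len(v)),
                    n_control=len(ctrl),
                    n_group=len(v),
                    statistic=float(stat),
                    p_raw=float(p),
                    p_adj=_bonferroni(float(p), m),
                    test="ANOVA + Bonferroni post hoc t",
                    tie=bool(tie),
                )
            )
    return pd.DataFrame(rows)
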