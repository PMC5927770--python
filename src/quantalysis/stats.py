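"""The two comparison procedures used throughout: Student's t and one-way
ANOVA with Tukey's HSD.  Thin, typed wrappers over scipy with the group
summaries (mean ± SEM, n) carried alongside the statistic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatResult:
    label: str
    test: str                       # "t_test" or "anova_tukey"
    statistic: float
    p_value: float
    group_means: list = field(default_factory=list)
    group_sems: list = field(default_factory=list)
    group_ns: list = field(default_factory=list)
    pairwise: list = field(default_factory=list)  # (i, j, adjusted p) for Tukey

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def _summaries(groups):
    means = [float(np.mean(g)) for g in groups]
    sems = [float(sps.sem(g)) if len(g) > 1 else np.nan for g in groups]
    ns = [len(g) for g in groups]
    return means, sems, ns


def two_group_test(a, b, label: str = "", equal_var: bool = True) -> StatResult:
    """Student's t test (two-sided); Welch via ``equal_var=False``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero within-group variance in all groups")
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    means, sems, ns = _summaries([a, b])
    return StatResult(label=label, test="t_test", statistic=float(t),
                      p_value=float(p), group_means=means, group_sems=sems,
                      group_ns=ns)


def anova_tukey(groups, label: str = "") -> StatResult:
    """One-way ANOVA followed by Tukey's multiple-comparison test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    if all(np.var(g, ddof=1) == 0 for g in groups):
        raise ValueError("zero within-group variance in all groups")
    f, p = sps.f_oneway(*groups)
    hsd = sps.tukey_hsd(*groups)
    pairwise = [(i, j, float(hsd.pvalue[i, j]))
                for i in range(len(groups)) for j in range(i + 1, len(groups))]
    means, sems, ns = _summaries(groups)
    return StatResult(label=label, test="anova_tukey", statistic=float(f),
                      p_value=float(p), group_means=means, group_sems=sems,
                      group_ns=ns, pairwise=pairwise)
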