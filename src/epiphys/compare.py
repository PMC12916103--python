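"""Delegated standard statistics: thin wrappers, no bespoke inference.

Group comparisons in this package's reports use unpaired t-tests,
repeated-measures two-way ANOVA with Sidak-corrected pairwise follow-ups,
or Fisher's exact test — all delegated to scipy/statsmodels.  Star
annotations (* p<0.05, ** p<0.01, *** p<0.001) are display only; nothing in
the package branches on them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def unpaired_t(a, b) -> dict:
    """Two-sided unpaired t-test with the mean difference as effect size."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = stats.ttest_ind(a, b)
    return {"test": "unpaired_t", "t": float(t), "p": float(p),
            "effect": float(a.mean() - b.mean()),
            "stars": significance_stars(float(p))}


def sidak_adjust(p_values) -> np.ndarray:
    """Sidak multiple-comparison adjustment: 1 - (1-p)^m."""
    p = np.asarray(p_values, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


def rm_anova_sidak(df: pd.DataFrame, *, dv: str, subject: str,
                   within: str, between: str) -> dict:
    """Repeated-measures two-way comparison with Sidak-corrected follow-ups.

    A mixed ANOVA (one between-subject factor such as genotype, one
    within-subject factor such as stimulus level) via statsmodels' OLS anova
    on the subject-aggregated data, followed by per-level unpaired t-tests
    with Sidak adjustment.  This is delegated standard statistics; the
    bespoke science lives elsewhere.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    work = df.rename(columns={dv: "_dv", subject: "_subj",
                              within: "_within", between: "_between"})
    model = ols("_dv ~ C(_between) * C(_within)", data=work).fit()
    table = sm.stats.anova_lm(model, typ=2)
    levels = sorted(work["_within"].unique())
    raw_p = []
    for lev in levels:
        sub = work[work["_within"] == lev]
        groups = [g["_dv"].to_numpy() for _, g in sub.groupby("_between")]
        if len(groups) == 2 and min(len(g) for g in groups) > 1:
            raw_p.append(float(stats.ttest_ind(*groups)[1]))
        else:
            raw_p.append(np.nan)
    adj = sidak_adjust(np.asarray(raw_p))
    return {"anova": table,
            "pairwise": pd.DataFrame({"level": levels, "p_raw": raw_p,
                                      "p_sidak": adj})}
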