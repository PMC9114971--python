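"""Group statistics for limb metrics.

Rule-based test selection, made explicit: every metric is screened per
group with a Shapiro-Wilk normality test at alpha = 0.05; if normality is
not rejected in any group a one-way ANOVA compares the groups, otherwise a
Kruskal-Wallis test is used (the non-parametric route the proliferating
cell counts take).  No multiple-testing correction is applied across
metrics; each metric is reported on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_NORMALITY = 0.05


@dataclass
class TestResult:
    metric: str
    test: str  # "anova" or "kruskal"
    p_value: float
    normality_p: dict[str, float]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]


def choose_test(groups: dict[str, np.ndarray], metric: str = "") -> TestResult:
    """Select and run the comparison test for one metric.

    Shapiro-Wilk per group at alpha = 0.05; ANOVA iff no group rejects
    normality, else Kruskal-Wallis.  Constant samples (Shapiro undefined)
    fall back to Kruskal-Wallis with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in clean.items():
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    normality = {}
    degenerate = False
    for g, v in clean.items():
        if np.ptp(v) == 0:
            warnings.warn(f"constant data in group {g!r}; Shapiro-Wilk undefined")
            normality[g] = np.nan
            degenerate = True
        else:
            normality[g] = float(sps.shapiro(v).pvalue)
    if degenerate or any(p < ALPHA_NORMALITY for p in normality.values()):
        test = "kruskal"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(sps.kruskal(*clean.values()).pvalue)
        except ValueError:  # all values identical across groups
            p = 1.0
        if not np.isfinite(p):  # degenerate ties
            p = 1.0
    else:
        test = "anova"
        p = float(sps.f_oneway(*clean.values()).pvalue)
    return TestResult(
        metric=metric,
        test=test,
        p_value=p,
        normality_p=normality,
        group_means={g: float(v.mean()) for g, v in clean.items()},
        group_sds={g: float(v.std(ddof=1)) for g, v in clean.items()},
        group_ns={g: int(len(v)) for g, v in clean.items()},
    )


def stat_report(df: pd.DataFrame, metrics: list[str], group_col: str = "group") -> pd.DataFrame:
    """Run the selection rule + test for each metric column of a tidy table."""
    rows = []
    for m in metrics:
        groups = {g: sub[m].to_numpy() for g, sub in df.groupby(group_col, sort=False)}
        res = choose_test(groups, metric=m)
        row = {
            "metric": m,
            "test": res.test,
            "p_value": res.p_value,
        }
        for g in groups:
            row[f"shapiro_p_{g}"] = res.normality_p[g]
            row[f"mean_{g}"] = res.group_means[g]
            row[f"sd_{g}"] = res.group_sds[g]
            row[f"n_{g}"] = res.group_ns[g]
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["rule"] = (
        "Shapiro-Wilk per group at alpha=0.05; ANOVA iff normality not "
        "rejected in any group, else Kruskal-Wallis. No multiple-testing "
        "correction across metrics."
    )
    return out
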