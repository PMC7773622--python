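"""Univariate group comparisons and multicollinearity screening.

Each variable is compared between two groups with a normality-routed test: a
Shapiro-Wilk test is run per group, and if both groups look normal at the
routing level (0.05) an independent-samples t test is used, otherwise a
two-sided Mann-Whitney U test.  No multiple-comparison correction is applied;
p values are reported per variable as-is.  Pairwise Pearson correlations flag
strongly collinear feature pairs (default |r| > 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "route_and_test", "compare_groups", "correlation_screen"]


@dataclass
class ComparisonResult:
    variable: str
    stratum: str
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    test_used: str  # "t" | "mann_whitney"
    p_value: float
    normality_p: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "stratum": self.stratum,
            "mean_x": self.mean_x,
            "sd_x": self.sd_x,
            "mean_y": self.mean_y,
            "sd_y": self.sd_y,
            "test_used": self.test_used,
            "p_value": self.p_value,
            "normality_p_x": self.normality_p[0],
            "normality_p_y": self.normality_p[1],
        }


def route_and_test(
    x,
    y,
    alpha_norm: float = 0.05,
    variable: str = "",
    stratum: str = "all",
    equal_var: bool = True,
) -> ComparisonResult:
    """Normality-routed two-sample comparison of ``x`` vs ``y``.

    Shapiro-Wilk per group; both p >= ``alpha_norm`` routes to the pooled
    (Student) independent t test (``equal_var=False`` gives Welch), otherwise
    to the two-sided Mann-Whitney U.  A zero-variance group cannot go down the
    t route and is diverted to Mann-Whitney with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance group; routing to Mann-Whitney U", stacklevel=2)
        sw_x = 0.0 if np.ptp(x) == 0 else float(stats.shapiro(x).pvalue)
        sw_y = 0.0 if np.ptp(y) == 0 else float(stats.shapiro(y).pvalue)
        use_t = False
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns on near-constant input
            sw_x = float(stats.shapiro(x).pvalue)
            sw_y = float(stats.shapiro(y).pvalue)
        use_t = sw_x >= alpha_norm and sw_y >= alpha_norm
    if use_t:
        p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
        test = "t"
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        test = "mann_whitney"
    return ComparisonResult(
        variable=variable,
        stratum=stratum,
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)),
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)),
        test_used=test,
        p_value=p,
        normality_p=(sw_x, sw_y),
    )


def compare_groups(
    features: pd.DataFrame,
    group_col: str,
    strata_col: str | None = None,
    alpha_norm: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`route_and_test` for every numeric column, per stratum.

    The group column must take exactly two values; comparisons are reported
    for all subjects together and, if ``strata_col`` is given, within each
    stratum as well.
    """
    groups = sorted(features[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"group column must have exactly 2 levels, found {groups}")
    value_cols = [
        c
        for c in features.columns
        if c not in (group_col, strata_col) and pd.api.types.is_numeric_dtype(features[c])
    ]
    strata = [("all", features)]
    if strata_col is not None:
        strata += [(str(s), sub) for s, sub in features.groupby(strata_col)]
    rows = []
    for name, sub in strata:
        gx = sub[sub[group_col] == groups[0]]
        gy = sub[sub[group_col] == groups[1]]
        for col in value_cols:
            res = route_and_test(
                gx[col].dropna(), gy[col].dropna(), alpha_norm, variable=col, stratum=name
            )
            rows.append(res.as_dict())
    return pd.DataFrame(rows)


def correlation_screen(
    features: pd.DataFrame, threshold: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations plus flags for |r| above ``threshold``.

    Constant columns yield undefined (NaN) correlations, reported as missing
    and never flagged.
    """
    numeric = features.select_dtypes(include=[np.number])
    if len(numeric.dropna()) < 3:
        raise ValueError("need at least 3 complete rows")
    corr = numeric.corr(method="pearson")
    flags = []
    cols = corr.columns
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = corr.iloc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                flags.append({"var_a": cols[a], "var_b": cols[b], "r": float(r)})
    return corr, pd.DataFrame(flags, columns=["var_a", "var_b", "r"])
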