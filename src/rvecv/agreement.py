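"""Method-comparison statistics: correlation, Bland-Altman, observer tables.

Conventions: differences are ``d = x - y`` with the method order explicit
in the caller's arguments, so swapping the inputs negates the bias and
mirrors the limits of agreement.  Limits of agreement use the conventional
1.96 multiplier on the sample SD of the differences; the 95% CI of the
bias uses the t distribution with n-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementResult", "correlation", "bland_altman", "observer_variability"]


@dataclass
class AgreementResult:
    """Correlation plus Bland-Altman agreement for one paired comparison."""

    n_pairs: int
    pearson_r: float
    spearman_rho: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias_low: float
    ci_bias_high: float


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Product-moment or rank correlation with a two-sided p value.

    Non-finite pairs are dropped; fewer than 3 finite pairs or zero
    variance in either vector is an error.
    """
    x, y = _paired_finite(x, y)
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(res.statistic), float(res.pvalue)


def bland_altman(x, y) -> AgreementResult:
    """Bland-Altman agreement of two paired measurement series.

    ``bias = mean(x - y)``, ``sd_diff`` is the sample SD (ddof=1) of the
    differences, limits of agreement are ``bias +/- 1.96 * sd_diff`` and
    the bias CI is t-based.  Correlations of the paired values are
    attached when both vectors have spread (NaN otherwise).
    """
    x, y = _paired_finite(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 finite pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    t = stats.t.ppf(0.975, n - 1)
    se = sd / np.sqrt(n)
    if np.ptp(x) > 0 and np.ptp(y) > 0:
        r, _ = correlation(x, y, "pearson")
        rho, _ = correlation(x, y, "spearman")
    else:
        r = rho = np.nan
    return AgreementResult(
        n_pairs=n,
        pearson_r=r,
        spearman_rho=rho,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half,
        loa_high=bias + half,
        ci_bias_low=bias - t * se,
        ci_bias_high=bias + t * se,
    )


def observer_variability(
    rater1_t1: pd.DataFrame,
    rater1_t2: pd.DataFrame,
    rater2: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Intra- and interobserver variability table.

    Inputs are DataFrames indexed by subject with one column per measured
    quantity (e.g. RV ECV by ROI, RV ECV by LOI, LV ECV).  Intraobserver
    rows compare the first rater's two sessions; interobserver rows
    compare the first rater's first session with the second rater.
    Subjects missing from a comparison are excluded and reported in the
    returned list of ``(comparison, subject)`` tuples.
    """
    rows, excluded = [], []
    comparisons = [
        ("intraobserver", rater1_t1, rater1_t2),
        ("interobserver", rater1_t1, rater2),
    ]
    for label, a, b in comparisons:
        common = a.index.intersection(b.index)
        for key in a.index.symmetric_difference(b.index):
            excluded.append((label, key))
        for quantity in a.columns:
            if quantity not in b.columns:
                continue
            res = bland_altman(a.loc[common, quantity], b.loc[common, quantity])
            rows.append(
                {"comparison": label, "quantity": quantity, "n": res.n_pairs,
                 "bias": res.bias, "sd_diff": res.sd_diff,
                 "ci_bias_low": res.ci_bias_low, "ci_bias_high": res.ci_bias_high,
                 "loa_low": res.loa_low, "loa_high": res.loa_high,
                 "r": res.pearson_r}
            )
    return pd.DataFrame(rows), excluded
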