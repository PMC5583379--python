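"""Agreement statistics between predicted and reference ablation areas.

For each candidate death-probability level the predicted areas (A_IRE) are
compared against the reference areas (A_HE, e.g. histology-derived) across
cases by (i) ordinary least-squares regression of A_IRE on A_HE and (ii)
Bland-Altman analysis of the pairwise differences with ±1.96 SD limits of
agreement, including the correlation of difference against pairwise mean
(a proportional-bias check).  The working level is then chosen as the one
maximizing the regression R², with ties broken by the smallest absolute
Bland-Altman mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .damage import AreaRecord

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "fit_regression",
    "bland_altman",
    "select_best_level",
]

#: Two-sided significance threshold used when flagging results.
ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    p_level: float
    n: int
    through_origin: bool = False

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "p_level": self.p_level,
            "n": self.n,
            "through_origin": self.through_origin,
        }


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r_diff_vs_mean: float | None
    p_diff_vs_mean: float | None
    p_level: float
    n: int

    @property
    def proportional_bias_computable(self) -> bool:
        return self.r_diff_vs_mean is not None

    def as_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "r_diff_vs_mean": self.r_diff_vs_mean,
            "p_diff_vs_mean": self.p_diff_vs_mean,
            "p_level": self.p_level,
            "n": self.n,
        }


def _paired_arrays(records: list[AreaRecord]) -> tuple[np.ndarray, np.ndarray, float]:
    if len(records) < 3:
        raise ValueError("need at least 3 paired records")
    levels = {r.p for r in records}
    if len(levels) != 1:
        raise ValueError(f"records mix probability levels: {sorted(levels)}")
    a_he = np.array([r.a_he for r in records], dtype=float)
    a_ire = np.array([r.a_ire for r in records], dtype=float)
    if not (np.all(np.isfinite(a_he)) and np.all(np.isfinite(a_ire))):
        raise ValueError("areas must be finite (a_he unset?)")
    return a_he, a_ire, levels.pop()


def fit_regression(
    records: list[AreaRecord],
    through_origin: bool = False,
    predictor: str = "a_he",
) -> RegressionResult:
    """OLS fit of predicted on reference areas at one probability level.

    By default the reference area is the predictor (x) and the predicted area
    the response (y), with an intercept; ``through_origin`` forces the line
    through zero and ``predictor="a_ire"`` swaps the roles.
    """
    a_he, a_ire, level = _paired_arrays(records)
    if predictor == "a_he":
        x, y = a_he, a_ire
    elif predictor == "a_ire":
        x, y = a_ire, a_he
    else:
        raise ValueError("predictor must be 'a_he' or 'a_ire'")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the predictor areas")

    n = len(x)
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        resid = y - slope * x
        # R^2 against the uncentered total sum of squares (no-intercept fit)
        ss_res = float(np.dot(resid, resid))
        ss_tot = float(np.dot(y, y))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        dof = n - 1
        se = np.sqrt(ss_res / dof / np.dot(x, x)) if dof > 0 else np.nan
        t = slope / se if se > 0 else np.inf
        p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
        return RegressionResult(slope, 0.0, float(np.clip(r2, 0, 1)), p, level, n, True)

    if np.ptp(y) == 0:
        # constant response: the fit explains nothing, by convention R^2 = 0
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, level, n)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        p_level=level,
        n=n,
    )


def bland_altman(records: list[AreaRecord]) -> BlandAltmanResult:
    """Bland-Altman agreement of predicted vs reference areas.

    Differences are ``a_ire - a_he``; limits of agreement are the mean
    difference ±1.96 sample standard deviations (n-1 denominator).  The
    difference-vs-mean Pearson correlation is reported with its two-sided p;
    when either variable is constant the correlation is not computable and is
    returned as ``None``.
    """
    a_he, a_ire, level = _paired_arrays(records)
    diff = a_ire - a_he
    pair_mean = (a_ire + a_he) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    scale_d = max(1.0, float(np.abs(diff).max()))
    scale_m = max(1.0, float(np.abs(pair_mean).max()))
    if np.ptp(diff) <= 1e-12 * scale_d or np.ptp(pair_mean) <= 1e-12 * scale_m:
        # constant differences (or means): proportional bias is undefined
        r, p = None, None
    else:
        r_, p_ = stats.pearsonr(diff, pair_mean)
        r, p = float(r_), float(p_)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        r_diff_vs_mean=r,
        p_diff_vs_mean=p,
        p_level=level,
        n=len(diff),
    )


def select_best_level(
    results_by_level: dict[float, tuple[RegressionResult, BlandAltmanResult]],
) -> dict:
    """Choose the working probability level.

    Maximizes R²; ties (to within 1e-12) are broken by the smallest absolute
    Bland-Altman mean difference.  Returns the chosen level with the criteria
    values recorded for the rationale.
    """
    if not results_by_level:
        raise ValueError("no levels analyzed")

    def key(item):
        level, (reg, ba) = item
        return (-round(reg.r_squared / 1e-12) * 1e-12, abs(ba.mean_diff), level)

    best_level, (reg, ba) = min(results_by_level.items(), key=key)
    return {
        "p_level": best_level,
        "r_squared": reg.r_squared,
        "slope": reg.slope,
        "mean_diff": ba.mean_diff,
        "criteria": "max R^2, ties by min |mean_diff|",
    }
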