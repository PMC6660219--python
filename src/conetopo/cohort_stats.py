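"""Cohort-level regressions, summaries and power analysis.

Per-eye records (biometry, RMF, peak and PRL cone densities, PRL
displacement, optionally BCEA) are analysed with simple linear regressions
against axial length.  Because some subjects contribute both eyes, a
one-eye-per-subject sensitivity analysis reruns the headline regressions on
a single eye per subject; pooling both eyes treats them as independent,
which slightly understates standard errors (documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "RegressionResult",
    "ols_fit",
    "cohort_summary",
    "one_eye_sensitivity",
    "sample_size_regression",
    "HEADLINE_REGRESSIONS",
]

# headline density-vs-axial-length relationships: y column -> label
HEADLINE_REGRESSIONS = {
    "peak_angular_density": "peak angular density vs axial length",
    "peak_linear_density": "peak linear density vs axial length",
    "prl_angular_density": "PRL angular density vs axial length",
    "prl_linear_density": "PRL linear density vs axial length",
}


@dataclass(frozen=True)
class RegressionResult:
    """Simple (one-predictor) OLS fit with t-based inference, n-2 df."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    p_value: float
    r_squared: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def ols_fit(x, y, alpha: float = 0.05) -> RegressionResult:
    """Ordinary least squares of y on x with slope CI and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=alpha)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=len(x),
    )


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise mean / min / max / SD of every numeric cohort column.

    SD is NaN (flagged, not an error) for a single-row table.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame(
        {
            "mean": num.mean(),
            "min": num.min(),
            "max": num.max(),
            "sd": num.std(ddof=1),
            "n": num.count(),
        }
    )


def one_eye_sensitivity(
    table: pd.DataFrame,
    selector: str = "first",
    seed: int | None = None,
    x_col: str = "axial_length_mm",
    y_cols: tuple[str, ...] = tuple(HEADLINE_REGRESSIONS),
) -> dict[str, RegressionResult]:
    """Rerun the headline regressions on one eye per subject.

    ``selector="first"`` keeps each subject's first-listed eye;
    ``selector="random"`` draws one eye per subject using ``seed``.
    """
    if selector not in ("first", "random"):
        raise ValueError("selector must be 'first' or 'random'")
    if selector == "first":
        sub = table.groupby("subject", sort=False).head(1)
    else:
        rng = np.random.default_rng(seed)
        idx = [
            rng.choice(g.index.to_numpy())
            for _, g in table.groupby("subject", sort=False)
        ]
        sub = table.loc[idx]
    return {c: ols_fit(sub[x_col], sub[c]) for c in y_cols if c in sub.columns}


def sample_size_regression(
    slope: float,
    sd_errors: float,
    sd_x: float,
    alpha: float = 0.05,
    power: float = 0.95,
) -> tuple[float, int]:
    """Sample size to detect a regression slope (normal approximation).

    Dupont–Plummer style calculation: with residual SD ``sd_errors`` and
    predictor SD ``sd_x``,

        n = (z_{1-alpha/2} + z_power)^2 * sd_errors^2 / (slope^2 * sd_x^2)

    Returns ``(exact, ceil)``; the exact value is the real-valued
    requirement, the integer is rounded up.
    """
    if slope == 0:
        raise ValueError("zero slope implies an infinite sample size")
    if sd_errors <= 0 or sd_x <= 0:
        raise ValueError("standard deviations must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z = norm.ppf(1 - alpha / 2) + norm.ppf(power)
    n = z**2 * sd_errors**2 / (slope**2 * sd_x**2)
    return float(n), int(ceil(n))
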