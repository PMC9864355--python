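"""Bland–Altman method-comparison statistics for paired CO measurements.

Agreement between two methods measuring the same quantity is summarised by
the mean difference (bias), the SD of the differences and the limits of
agreement bias ± 1.96·SD, which bracket ~95% of differences when the
differences are normal.  A proportional bias — differences trending with
the magnitude of the measurement — is screened by ordinary least squares of
the differences on the pair means; normality of the differences is checked
with a Shapiro–Wilk statistic (advisory, the primary check being visual).

Differences are oriented ``method_a − method_b``; with method_a = CO_TD and
method_b = CO_DF this matches the model's X = CO_TD − CO_DF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import LOA_FACTOR
from .exceptions import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class BASummary:
    """Bland–Altman summary of paired measurements.

    Attributes
    ----------
    n : int
        Number of pairs.
    bias : float
        Mean difference method_a − method_b (L/min).
    sd_diff : float
        SD of the differences (n−1 denominator, L/min).
    loa : float
        1.96 × sd_diff (L/min).
    loa_interval : tuple of float
        (bias − loa, bias + loa).
    prop_slope : float or None
        OLS slope of differences on pair means; None if undefined
        (fewer than 3 pairs or zero variance of the means).
    prop_slope_ci : tuple of float or None
        95% confidence interval of the slope.
    normality_stat, normality_p : float or None
        Shapiro–Wilk W statistic and p-value for the differences.
    """

    n: int
    bias: float
    sd_diff: float
    loa: float
    loa_interval: tuple[float, float]
    prop_slope: float | None
    prop_slope_ci: tuple[float, float] | None
    normality_stat: float | None
    normality_p: float | None


class BlandAltman(BaseEstimator):
    """Bland–Altman agreement estimator for paired measurements.

    ``fit`` takes an (n, 2) array (columns: method_a, method_b) or a
    DataFrame whose first two columns are the paired measurements, and
    exposes the summary statistics as fitted attributes (``bias_``,
    ``sd_diff_``, ``loa_``, ``loa_interval_``, ``prop_slope_``,
    ``prop_slope_ci_``, ``normality_stat_``, ``normality_p_``).

    Parameters
    ----------
    loa_factor : float, default 1.96
        Multiplier converting the SD of differences to the limits of
        agreement half-width.
    """

    def __init__(self, loa_factor: float = LOA_FACTOR):
        self.loa_factor = loa_factor

    def fit(self, X, y=None) -> "BlandAltman":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidInputError(
                f"expected an (n, 2) array of paired measurements, "
                f"got shape {X.shape}"
            )
        if X.shape[0] < 2:
            raise InsufficientDataError(
                f"need at least 2 pairs, got {X.shape[0]}"
            )
        if not np.all(np.isfinite(X)) or np.any(X <= 0):
            raise InvalidInputError("measurements must be finite and > 0")
        a, b = X[:, 0], X[:, 1]
        diff = a - b
        mean = (a + b) / 2.0
        n = diff.size

        self.n_ = n
        self.differences_ = diff
        self.means_ = mean
        self.bias_ = float(np.mean(diff))
        self.sd_diff_ = float(np.std(diff, ddof=1))
        self.loa_ = self.loa_factor * self.sd_diff_
        self.loa_interval_ = (self.bias_ - self.loa_, self.bias_ + self.loa_)

        # Proportional-bias screen: OLS of differences on means.
        if n >= 3 and np.ptp(mean) > 0:
            res = stats.linregress(mean, diff)
            tcrit = stats.t.ppf(0.975, n - 2)
            self.prop_slope_ = float(res.slope)
            self.prop_slope_ci_ = (
                float(res.slope - tcrit * res.stderr),
                float(res.slope + tcrit * res.stderr),
            )
        else:
            self.prop_slope_ = None
            self.prop_slope_ci_ = None

        if n >= 3 and np.ptp(diff) > 0:
            # W is only accurate up to n ~ 5000; use a deterministic
            # evenly spaced subsample beyond that (the test is advisory).
            sample = diff
            if n > 5000:
                sample = diff[np.linspace(0, n - 1, 5000).astype(int)]
            w, p = stats.shapiro(sample)
            self.normality_stat_ = float(w)
            self.normality_p_ = float(p)
        else:
            self.normality_stat_ = None
            self.normality_p_ = None
        return self

    def summary(self) -> BASummary:
        """Return the fitted statistics as an immutable summary."""
        check_is_fitted(self, "bias_")
        return BASummary(
            n=self.n_,
            bias=self.bias_,
            sd_diff=self.sd_diff_,
            loa=self.loa_,
            loa_interval=self.loa_interval_,
            prop_slope=self.prop_slope_,
            prop_slope_ci=self.prop_slope_ci_,
            normality_stat=self.normality_stat_,
            normality_p=self.normality_p_,
        )


def bland_altman(method_a, method_b) -> BASummary:
    """Bland–Altman summary for two equal-length sequences of measurements."""
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError(
            "method_a and method_b must be 1-d sequences of equal length"
        )
    return BlandAltman().fit(np.column_stack([a, b])).summary()


def proportional_bias_detected(summary: BASummary) -> bool | None:
    """Whether the slope of differences on means is significantly non-zero.

    Returns True when the slope's 95% CI excludes zero, False when it
    contains zero, and None (indeterminate) when the slope is undefined.
    """
    if summary.prop_slope is None or summary.prop_slope_ci is None:
        return None
    lo, hi = summary.prop_slope_ci
    return bool(lo > 0.0 or hi < 0.0)
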