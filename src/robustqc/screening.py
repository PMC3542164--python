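"""Robust univariate outlier screens: IQR, MAD, and one-dimensional MCD.

All three screens compare a per-observation statistic to a fixed critical
value chosen so that about 2.5% of clean normal data is flagged:

* IQR screen:  |x_i - center| / (IQR / 1.355)  >= 2.24
* MAD screen:  |x_i - center| / (MAD / 0.666)  >= 2.24
* MCD screen:  (x_i - T)^2 / C                 >= 5.02

2.24 is the standard-normal 0.9875 quantile (1.25% in each tail) and 5.02 the
chi-squared(1 df) upper 2.5% point. The divisors 1.355 and 0.666 make IQR and
MAD consistent estimates of the normal standard deviation at large n. The MCD
location T and scatter C come from the h-observation subset of minimal
variance; in one dimension that optimum is a contiguous window of the sorted
sample, so it is found exactly by scanning all n-h+1 windows. The raw subset
variance is multiplied by a consistency factor so that C estimates sigma^2
under normality, which is what lets the chi-squared cutoff hold its nominal
level.

A screen on data whose robust scale collapses to zero (e.g. more than half
zeros, common for rare-event indicators) cannot flag anything; it reports
``status="failed"`` with all flags false rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sample import IndicatorSample

#: Swallow-Kianifard large-sample divisors making IQR and MAD estimate sigma.
DEFAULT_IQR_DIVISOR = 1.355
DEFAULT_MAD_DIVISOR = 0.666

#: Standard-normal 0.9875 quantile, rounded: two-sided 2.5% rule for IQR/MAD.
DEFAULT_IQR_MAD_CUTOFF = 2.24
#: chi-squared(1) upper 2.5% quantile, rounded: cutoff for squared distances.
DEFAULT_MCD_CUTOFF = 5.02

#: chi-squared(1) quantile used for the one-step reweighting of the MCD fit.
_REWEIGHT_QUANTILE = stats.chi2.ppf(0.975, df=1)


class DegenerateScatterError(ValueError):
    """Raised when distances are requested from a zero-scatter fit."""


@dataclass(frozen=True)
class ScaleFit:
    """A robust location/scale estimate for the IQR or MAD screen."""

    method: str
    location_T: float
    scale_sigma_hat: float
    divisor: float
    status: str  # "ok" | "degenerate"

    def __post_init__(self) -> None:
        assert (self.status == "degenerate") == (self.scale_sigma_hat == 0.0)


@dataclass(frozen=True)
class MCDFit:
    """The exact one-dimensional MCD solution.

    ``raw_T``/``raw_C`` are the mean and variance of the optimal h-window of
    the sorted sample; ``corrected_C`` is the raw variance rescaled by the
    consistency factor; ``final_T``/``final_C`` are the estimates the screen
    uses (one-step reweighted when ``reweighted`` is true, otherwise the raw
    corrected ones).
    """

    n: int
    p: int
    h: int
    window_start: int
    raw_T: float
    raw_C: float
    consistency_factor: float
    corrected_C: float
    reweighted: bool
    final_T: float
    final_C: float
    status: str  # "ok" | "degenerate"


@dataclass(frozen=True)
class ScreeningResult:
    """Per-observation screening statistics and flags.

    When ``status`` is ``"failed"`` (degenerate scale), ``statistics`` is
    ``None`` and every flag is false.
    """

    method: str
    statistics: np.ndarray | None
    cutoff: float
    flags: np.ndarray
    n_flagged: int
    status: str  # "ok" | "failed"


def _check_sample(sample: IndicatorSample) -> np.ndarray:
    if len(sample) == 0:
        raise ValueError("sample must be nonempty")
    return sample.values


def _location(x: np.ndarray, center: str) -> float:
    if center == "mean":
        return float(np.mean(x))
    if center == "median":
        return float(np.median(x))
    raise ValueError(f"unknown center: {center!r}")


def iqr_scale(
    sample: IndicatorSample,
    divisor: float = DEFAULT_IQR_DIVISOR,
    center: str = "mean",
    quantile_method: str = "linear",
) -> ScaleFit:
    """Interquartile-range scale estimate: (q75 - q25) / divisor.

    ``quantile_method`` is passed to :func:`numpy.percentile`; at the sample
    sizes screened here the conventions differ negligibly. The fit is
    degenerate when the quartiles coincide (e.g. >= 75% identical values).
    """
    x = _check_sample(sample)
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    q25, q75 = np.percentile(x, [25, 75], method=quantile_method)
    scale = float(q75 - q25) / divisor
    status = "degenerate" if scale == 0.0 else "ok"
    return ScaleFit(
        method="iqr",
        location_T=_location(x, center),
        scale_sigma_hat=scale,
        divisor=divisor,
        status=status,
    )


def mad_scale(
    sample: IndicatorSample,
    divisor: float = DEFAULT_MAD_DIVISOR,
    center: str = "mean",
) -> ScaleFit:
    """Median-absolute-deviation scale estimate: median|x - median(x)| / divisor.

    Degenerate as soon as more than half the observations equal the median —
    the failure mode of zero-inflated rare-event indicators.
    """
    x = _check_sample(sample)
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    med = np.median(x)
    mad = float(np.median(np.abs(x - med)))
    scale = mad / divisor
    status = "degenerate" if scale == 0.0 else "ok"
    return ScaleFit(
        method="mad",
        location_T=_location(x, center),
        scale_sigma_hat=scale,
        divisor=divisor,
        status=status,
    )


def consistency_factor(h_fraction: float) -> float:
    """Multiplier making the best-h-subset variance consistent for sigma^2.

    Under normality the optimal h-subset is asymptotically the central
    h_fraction of the distribution, whose variance understates sigma^2; the
    factor h_fraction / F_chi2_3(q) with q the chi-squared(1) quantile at
    h_fraction corrects this (1 at h_fraction = 1, about 7.0 at 0.5).
    """
    if not 0.0 < h_fraction <= 1.0:
        raise ValueError("h_fraction must lie in (0, 1]")
    if h_fraction == 1.0:
        return 1.0
    q = stats.chi2.ppf(h_fraction, df=1)
    return float(h_fraction / stats.chi2.cdf(q, df=3))


def default_h(n: int, p: int = 1) -> int:
    """Maximum-breakdown subset size floor((n + p + 1) / 2)."""
    return (n + p + 1) // 2


def mcd_univariate(
    sample: IndicatorSample, h: int | None = None, reweight: bool = True
) -> MCDFit:
    """Exact minimum-covariance-determinant fit in one dimension.

    Sorts the sample and scans every contiguous window of length ``h``; the
    minimum-variance window is the exact MCD subset (ties broken towards the
    lowest start index). The n - h largest or smallest observations can be
    made arbitrarily extreme without moving the fit, giving the estimator its
    high breakdown point.

    With ``reweight=True`` a one-step reweighting recomputes location and
    scatter from all observations whose squared distance under the corrected
    raw fit is below the chi-squared(1) 0.975 quantile, with the analogous
    consistency correction.
    """
    x = _check_sample(sample)
    n = x.size
    p = 1
    if n < 3:
        raise ValueError("MCD requires at least 3 observations")
    if h is None:
        h = default_h(n, p)
    if not default_h(n, p) <= h <= n:
        raise ValueError(
            f"h must lie in [{default_h(n, p)}, {n}] for n={n}, got {h}"
        )
    xs = np.sort(x)
    # Prefix sums on median-centred values keep the window-variance scan
    # O(n). Centring on the median keeps the candidate (bulk) windows at
    # small magnitudes, so their variances survive the cancellation in the
    # prefix differences even when n - h observations are grossly extreme;
    # the selected window's statistics are then recomputed directly.
    c = xs - np.median(xs)
    s1 = np.concatenate([[0.0], np.cumsum(c)])
    s2 = np.concatenate([[0.0], np.cumsum(c * c)])
    win_sum = s1[h:] - s1[:-h]
    win_sq = s2[h:] - s2[:-h]
    win_var = (win_sq - win_sum**2 / h) / (h - 1)
    start = int(np.argmin(win_var))
    window = xs[start : start + h]
    raw_T = float(window.mean())
    raw_C = float(window.var(ddof=1))
    factor = consistency_factor(h / n)
    corrected_C = raw_C * factor

    final_T, final_C = raw_T, corrected_C
    did_reweight = False
    if reweight and corrected_C > 0.0:
        d2 = (x - raw_T) ** 2 / corrected_C
        keep = x[d2 <= _REWEIGHT_QUANTILE]
        if keep.size >= 2:
            final_T = float(keep.mean())
            final_C = float(keep.var(ddof=1)) * consistency_factor(0.975)
            did_reweight = True
    return MCDFit(
        n=n,
        p=p,
        h=h,
        window_start=start,
        raw_T=raw_T,
        raw_C=raw_C,
        consistency_factor=factor,
        corrected_C=corrected_C,
        reweighted=did_reweight,
        final_T=final_T,
        final_C=final_C,
        status="degenerate" if final_C == 0.0 else "ok",
    )


def robust_distances(sample: IndicatorSample, fit: MCDFit) -> np.ndarray:
    """Squared robust distances (x_i - T)^2 / C in input order."""
    if fit.status != "ok":
        raise DegenerateScatterError(
            "robust distances undefined: MCD scatter is zero"
        )
    x = _check_sample(sample)
    return (x - fit.final_T) ** 2 / fit.final_C


def screen(
    sample: IndicatorSample,
    method: str,
    cutoff: float | None = None,
    *,
    center: str = "mean",
    iqr_divisor: float = DEFAULT_IQR_DIVISOR,
    mad_divisor: float = DEFAULT_MAD_DIVISOR,
    quantile_method: str = "linear",
    h: int | None = None,
    reweight: bool = False,
) -> ScreeningResult:
    """Flag potential outliers in one indicator sample.

    For ``iqr`` and ``mad`` the statistic is |x - center| / sigma_hat with
    cutoff 2.24 (two-sided by construction); for ``mcd`` it is the squared
    robust distance with cutoff 5.02. An observation is flagged when its
    statistic reaches the cutoff. The MCD screen uses the raw
    consistency-corrected distances by default; pass ``reweight=True`` to
    flag on the one-step reweighted fit instead.

    A degenerate scale or scatter yields ``status="failed"`` and zero flags —
    the screen abstains rather than flagging arbitrarily.
    """
    x = _check_sample(sample)
    n = x.size
    if method in ("iqr", "mad"):
        if cutoff is None:
            cutoff = DEFAULT_IQR_MAD_CUTOFF
        if method == "iqr":
            fit = iqr_scale(
                sample,
                divisor=iqr_divisor,
                center=center,
                quantile_method=quantile_method,
            )
        else:
            fit = mad_scale(sample, divisor=mad_divisor, center=center)
        if fit.status == "degenerate":
            return _failed(method, cutoff, n)
        statistics = np.abs(x - fit.location_T) / fit.scale_sigma_hat
    elif method == "mcd":
        if cutoff is None:
            cutoff = DEFAULT_MCD_CUTOFF
        try:
            mcd_fit = mcd_univariate(sample, h=h, reweight=reweight)
        except ValueError:
            raise
        if mcd_fit.status == "degenerate":
            return _failed(method, cutoff, n)
        statistics = robust_distances(sample, mcd_fit)
    else:
        raise ValueError(f"unknown screening method: {method!r}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    flags = statistics >= cutoff
    return ScreeningResult(
        method=method,
        statistics=statistics,
        cutoff=float(cutoff),
        flags=flags,
        n_flagged=int(flags.sum()),
        status="ok",
    )


def _failed(method: str, cutoff: float, n: int) -> ScreeningResult:
    return ScreeningResult(
        method=method,
        statistics=None,
        cutoff=float(cutoff),
        flags=np.zeros(n, dtype=bool),
        n_flagged=0,
        status="failed",
    )
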