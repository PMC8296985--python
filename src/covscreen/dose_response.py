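"""Four-parameter logistic dose-response fits and drug sensitivity scores.

The model is the "log(inhibitor) vs. response, variable slope" equation

    y(x) = bottom + (top - bottom) / (1 + 10^(hill * (m - x)))

with ``x = log10(concentration in M)`` and ``m = log10(IC50)``.  A positive
Hill slope gives an ascending (inhibition-style) curve; a negative slope a
descending one (e.g. probe displacement read as raw anisotropy).  Internally
fits are canonicalized so ``top >= bottom`` always, with the slope sign
carrying the direction.

Drug sensitivity scores (DSS) summarise a fitted curve as a normalized area
under the percent-inhibition curve above a minimal activity threshold ``t``
(10% by default) over the screened window ``[cmin, cmax]`` (log10 molar):

    DSS1 = (AUC - t*(x2 - x1)) / ((100 - t) * (cmax - cmin))
    DSS2 = DSS1 / log10(a)           (a = top asymptote, clamped to [t, 100])
    DSS3 = DSS2 * (x2 - x1) / (cmax - cmin)

where ``x2 = cmax`` and ``x1`` is the log-concentration at which the fitted
curve first reaches ``t`` (clamped to the window).  The AUC is the exact
closed-form integral of the logistic.  Scores are reported on a 0-100 scale.
DSS2 discounts curves whose asymptote falls short of complete inhibition, and
DSS3 additionally down-weights compounds active only in a narrow top-dose
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "LogisticFit", "DSSResult", "logistic4", "fit_logistic4",
    "auc_closed_form", "dss", "selectivity_ratio",
]

_LN10 = np.log(10.0)


def logistic4(x, bottom, top, hill, log10_mid):
    """Evaluate the 4PL curve at log10 concentration ``x`` (vectorized)."""
    z = _LN10 * hill * (log10_mid - np.asarray(x, dtype=float))
    # 1/(1+e^z) computed stably for large |z|
    return bottom + (top - bottom) * 0.5 * (1.0 - np.tanh(z / 2.0))


@dataclass
class LogisticFit:
    """Canonicalized 4PL parameters with fit diagnostics.

    ``top >= bottom``; ``hill`` is signed (negative for descending curves).
    ``ic50`` is ``10**log10_mid`` in molar.  ``inconclusive`` is set when the
    fit failed to converge or had fewer points than parameters; callers may
    additionally classify a converged fit as inconclusive in context (e.g.
    midpoint beyond the screened range).
    """

    bottom: float
    top: float
    hill: float
    log10_mid: float
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = True
    inconclusive: bool = False
    reason: str = ""

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log10_mid)

    def __call__(self, x):
        return logistic4(x, self.bottom, self.top, self.hill, self.log10_mid)


def _fit_one_direction(x, y, hill_sign, bounds):
    """Bounded least squares for one slope direction; multi-start on midpoint."""
    (blo, bhi), (tlo, thi) = bounds
    lo = [blo, tlo, 0.2, x.min() - 2.0]
    hi = [bhi, thi, 10.0, x.max() + 2.0]

    def model(x_, b, t, h, m):
        return logistic4(x_, b, t, hill_sign * h, m)

    span = x.max() - x.min()
    best = None
    for frac in (0.25, 0.5, 0.75):
        m0 = x.min() + frac * span
        p0 = [np.clip(y.min(), blo, bhi), np.clip(y.max(), tlo, thi), 1.0, m0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(model, x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    return best


def fit_logistic4(conc, response, *, bounds: str = "percent") -> LogisticFit:
    """Fit the 4PL model to (concentration [M], response) points.

    Parameters
    ----------
    conc, response:
        Concentrations (molar, > 0) and responses.  At least 4 distinct
        concentrations are required for a conclusive fit.
    bounds:
        ``"percent"`` (default) constrains bottom to [-10, 50] and top to
        [0, 120] — appropriate for percent inhibition/viability.  ``"auto"``
        derives bounds from the data range, for fits on raw signal scales
        such as anisotropy.

    Never raises on a poor fit: non-convergence or underdetermined input
    yields a fit flagged ``inconclusive`` (mirroring how screening tables
    report such compounds) rather than an exception.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.shape != y.shape:
        raise ValueError("conc and response must have the same length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (controls enter via normalization)")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    x = np.log10(conc)

    def _failed(reason):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, converged=False,
                           inconclusive=True, reason=reason)

    if len(np.unique(x)) < 4:
        return _failed("fewer than 4 distinct concentrations")

    if bounds == "percent":
        b = ((-10.0, 50.0), (0.0, 120.0))
    elif bounds == "auto":
        span = max(y.max() - y.min(), 1e-12)
        b = ((y.min() - span, y.min() + 0.5 * span),
             (y.max() - 0.5 * span, y.max() + span))
    else:
        raise ValueError("bounds must be 'percent' or 'auto'")

    candidates = []
    for sign in (+1.0, -1.0):
        res = _fit_one_direction(x, y, sign, b)
        if res is not None:
            candidates.append((sign, *res))
    if not candidates:
        return _failed("nonlinear least squares did not converge")

    sign, popt, pcov, rss = min(candidates, key=lambda c: c[3])
    bot, top, h, m = popt
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(("bottom", "top", "hill", "log10_mid"), map(float, perr)))
    return LogisticFit(float(bot), float(top), float(sign * h), float(m),
                       stderr=stderr, rss=rss, converged=True)


def auc_closed_form(fit: LogisticFit, lo: float, hi: float) -> float:
    """Exact integral of the fitted 4PL over [lo, hi] (log10 molar).

    The logistic has the elementary antiderivative

        F(x) = bottom*x + (top - bottom) * (x + softplus(ln10*h*(m-x)) / (h*ln10))

    since d/dx [softplus(ln10*h*(m-x))/(h*ln10)] = -10^(h(m-x)) / (1+10^(h(m-x)))
    and 1/(1+u) = 1 - u/(1+u).  Computed with log1p-style stabilisation so it
    never overflows for steep slopes.
    """
    if lo > hi:
        raise ValueError("integration bounds must satisfy lo <= hi")
    b, t, h, m = fit.bottom, fit.top, fit.hill, fit.log10_mid
    if h == 0 or t == b:
        return float(0.5 * (b + t) * (hi - lo))

    def F(x):
        return x + np.logaddexp(0.0, _LN10 * h * (m - x)) / (h * _LN10)

    return float(b * (hi - lo) + (t - b) * (F(hi) - F(lo)))


@dataclass
class DSSResult:
    """DSS1/2/3 on the 0-100 scale plus the quantities entering them."""

    dss1: float
    dss2: float
    dss3: float
    auc: float
    t: float
    a: float
    x1: float
    x2: float
    cmin: float
    cmax: float
    warning: str = ""


def _invert_at_threshold(fit: LogisticFit, t: float) -> float:
    """log10 concentration where the ascending 4PL first reaches response t."""
    b, top, h, m = fit.bottom, fit.top, fit.hill, fit.log10_mid
    # y = t  <=>  10^(h(m-x)) = (top - b)/(t - b) - 1
    u = (top - b) / (t - b) - 1.0
    return m - np.log10(u) / h


def dss(fit: LogisticFit, cmin: float, cmax: float, t: float = 10.0) -> DSSResult:
    """Drug sensitivity scores for an ascending percent-inhibition fit.

    Parameters
    ----------
    fit:
        Converged ascending 4PL fit of % inhibition vs log10 molar dose.
    cmin, cmax:
        log10 of the minimum/maximum screened concentration (molar).
    t:
        Minimal activity threshold in percent (default 10).

    Scores are 0 whenever the fitted curve never exceeds ``t`` within the
    screened window; negative numerators are floored at 0.
    """
    if not cmin < cmax:
        raise ValueError("cmin must be < cmax")
    zero = DSSResult(0.0, 0.0, 0.0, 0.0, t, np.nan, np.nan, cmax, cmin, cmax)
    if fit.inconclusive or not fit.converged:
        zero.warning = f"inconclusive fit: {fit.reason}"
        return zero
    if fit.hill < 0:
        raise ValueError("dss requires an ascending (inhibition) dose-response fit")

    a = float(np.clip(fit.top, t, 100.0))
    if a <= 1.0:
        zero.warning = "top asymptote <= 1 after clamping; score set to 0"
        zero.a = a
        return zero

    x2 = cmax
    if fit(cmax) < t:  # never reaches threshold in window
        zero.a = a
        return zero
    if fit(cmin) >= t:
        x1 = cmin
    else:
        x1 = float(np.clip(_invert_at_threshold(fit, t), cmin, cmax))

    auc = auc_closed_form(fit, x1, x2)
    width = cmax - cmin
    dss1 = max((auc - t * (x2 - x1)) / ((100.0 - t) * width), 0.0)
    dss2 = dss1 / np.log10(a)
    dss3 = dss2 * (x2 - x1) / width
    return DSSResult(100.0 * dss1, 100.0 * dss2, 100.0 * dss3,
                     auc, t, a, x1, x2, cmin, cmax)


def selectivity_ratio(a: DSSResult, b: DSSResult) -> float:
    """Ratio of DSS3 scores (e.g. KRAS-mutant over HRAS-mutant cell line).

    Returns NaN (with a warning) when the denominator score is 0, flagging an
    undefined ratio rather than raising.
    """
    if b.dss3 == 0:
        warnings.warn("selectivity ratio undefined: denominator DSS3 is 0")
        return float("nan")
    return a.dss3 / b.dss3
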