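"""Covalent-inhibition kinetics: kobs per dose, Ki and k2 globally.

A covalent inhibitor engages its target in two steps,

    E + I  <->  E.I  -->  E-I
          Ki         k2

with Ki the dissociation constant of the initial non-covalent complex and k2
the rate of the bond-forming step (assumed irreversible, k-2 = 0).  Under
pseudo-first-order conditions the probe signal decays exponentially with the
observed rate

    kobs = k2 * [I] / (Ki + [I]),

so a time course at each inhibitor concentration yields one kobs (one-phase
decay fit), and the hyperbolic dependence of kobs on [I] yields Ki and k2.
Their ratio k2/Ki is the second-order rate constant of covalent engagement —
the headline efficiency number for a covalent inhibitor.  Time is in hours
throughout (k2, kobs in h^-1; k2/Ki in M^-1 h^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeCourse", "KobsFit", "CovalentKinetics",
    "fit_kobs", "fit_ki_k2", "second_order_rate", "round_second_order",
    "kinetics_from_timecourses",
]


@dataclass(frozen=True)
class TimeCourse:
    """Signal vs incubation time at one inhibitor concentration.

    ``times`` in hours, strictly increasing, at least 4 samples;
    ``signals`` in anisotropy/polarization units.
    """

    inhibitor_conc: float
    times: tuple[float, ...]
    signals: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size < 4:
            raise ValueError("a time course needs at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.signals):
            raise ValueError("times and signals must have equal length")


@dataclass
class KobsFit:
    """One-phase decay fit y(t) = plateau + span * exp(-kobs * t)."""

    kobs: float
    span: float
    plateau: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    low_confidence: bool = False
    reason: str = ""


def _one_phase_decay(t, plateau, span, kobs):
    return plateau + span * np.exp(-kobs * t)


def fit_kobs(tc: TimeCourse) -> KobsFit:
    """Least-squares one-phase decay fit of a single time course.

    The plateau is left unconstrained.  A flat signal returns kobs = 0 with a
    low-confidence flag; non-convergence returns an inconclusive (flagged)
    fit rather than raising.
    """
    t = np.asarray(tc.times, dtype=float)
    y = np.asarray(tc.signals, dtype=float)
    span0 = y[0] - y[-1]
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        return KobsFit(0.0, 0.0, float(y.mean()), low_confidence=True,
                       reason="flat signal")
    # initial rate guess from the half-change time
    half = y[-1] + span0 / 2.0
    idx = np.argmin(np.abs(y - half))
    k0 = np.log(2.0) / max(t[idx], t[1] - t[0])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                _one_phase_decay, t, y, p0=[y[-1], span0, k0],
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return KobsFit(np.nan, np.nan, np.nan, converged=False,
                       low_confidence=True, reason="decay fit did not converge")
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(("plateau", "span", "kobs"), map(float, perr)))
    return KobsFit(float(popt[2]), float(popt[1]), float(popt[0]), stderr=stderr)


@dataclass
class CovalentKinetics:
    """Global two-step parameters with the per-dose kobs fits behind them."""

    ki: float
    k2: float
    second_order: float
    stderr: dict = field(default_factory=dict)
    kobs_fits: list = field(default_factory=list)
    saturating: bool = True
    warning: str = ""


def fit_ki_k2(conc, kobs, kobs_se=None, kobs_fits=None) -> CovalentKinetics:
    """Fit kobs = k2*[I]/(Ki + [I]) over inhibitor concentrations (molar).

    Points are weighted by inverse variance when kobs standard errors are
    supplied.  If no saturation is detectable (kobs effectively linear in
    [I], fitted Ki far above the probed range), only the second-order
    constant — the initial slope — is meaningful; Ki and k2 are then flagged
    unresolved (NaN) and the slope is reported.
    """
    conc = np.asarray(conc, dtype=float)
    kobs = np.asarray(kobs, dtype=float)
    if conc.size < 3:
        raise ValueError("need kobs at >= 3 concentrations")
    if np.any(conc <= 0):
        raise ValueError("inhibitor concentrations must be positive")

    sigma = None
    if kobs_se is not None:
        se = np.asarray(kobs_se, dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            sigma = se

    def hyperbola(i, k2, ki):
        return k2 * i / (ki + i)

    k2_0 = float(kobs.max()) or 1.0
    ki_0 = float(conc[np.argmin(np.abs(kobs - k2_0 / 2.0))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            hyperbola, conc, kobs, p0=[k2_0, ki_0], sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    k2, ki = map(float, popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(("k2", "ki"), map(float, perr)))

    top = conc.max()
    if ki > 10.0 * top:
        # linear regime: kobs ~ (k2/Ki) * [I]; only the slope is identified
        slope = float(np.sum(conc * kobs) / np.sum(conc * conc))
        return CovalentKinetics(
            np.nan, np.nan, slope, stderr=stderr, kobs_fits=list(kobs_fits or []),
            saturating=False,
            warning="no saturation over probed range; Ki and k2 unresolved, "
                    "second-order constant from initial slope",
        )
    if conc.min() > ki or top < ki:
        warnings.warn("kobs concentrations do not bracket the apparent Ki; "
                      "Ki and k2 may be poorly constrained")
    return CovalentKinetics(ki, k2, k2 / ki, stderr=stderr,
                            kobs_fits=list(kobs_fits or []))


def kinetics_from_timecourses(df) -> CovalentKinetics:
    """Full pipeline: tidy time-course table -> kobs per dose -> Ki, k2.

    ``df`` needs columns ``conc`` (molar), ``time_h`` and ``signal``;
    replicates (if any) are averaged per (conc, time) before the decay fits.
    Only converged kobs fits enter the hyperbolic stage, weighted by their
    standard errors when available.
    """
    avg = df.groupby(["conc", "time_h"], as_index=False)["signal"].mean()
    concs, kobs, kobs_se, fits = [], [], [], []
    for c, grp in avg.groupby("conc"):
        grp = grp.sort_values("time_h")
        fit = fit_kobs(TimeCourse(float(c), tuple(grp["time_h"]), tuple(grp["signal"])))
        fits.append(fit)
        if fit.converged and not fit.low_confidence:
            concs.append(float(c))
            kobs.append(fit.kobs)
            kobs_se.append(fit.stderr.get("kobs", np.nan))
    return fit_ki_k2(concs, kobs, kobs_se=kobs_se, kobs_fits=fits)


def second_order_rate(k2: float, ki: float) -> float:
    """Second-order rate constant k2/Ki (M^-1 h^-1); 0 when k2 = 0."""
    if ki <= 0:
        raise ValueError("ki must be positive")
    return k2 / ki


def round_second_order(rate: float) -> float:
    """Round a second-order constant to screening-table precision.

    Values are reported in multiples of 10^3 M^-1 h^-1 with two significant
    figures at or above 10 x 10^3 and one below, the convention used in
    covalent-kinetics summary tables (e.g. 13797 -> 14 x 10^3, 8974 -> 9 x 10^3).
    Returns the rounded value in M^-1 h^-1.
    """
    if rate == 0:
        return 0.0
    mantissa = rate / 1e3
    sig = 2 if abs(mantissa) >= 10 else 1
    ndigits = sig - int(np.floor(np.log10(abs(mantissa)))) - 1
    return round(mantissa, ndigits) * 1e3
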