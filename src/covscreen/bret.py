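"""BRET ratio computation, donor-saturation titrations and inhibition traces.

In a BRET experiment a luciferase-tagged donor excites a fluorescent-protein
acceptor only when the two are within nanometre proximity (here used to read
Ras nanoclustering or a protein-protein interaction in live cells).  The raw
BRET ratio is the acceptor-channel emission (515 nm) divided by the
donor-channel emission (410 nm, RLU); subtracting the same ratio measured in
donor-only cells removes the donor bleed-through background:

    BRET ratio = (515/410)_{donor+acceptor} - (515/410)_{donor only}

The acceptor expression relative to the donor is RFU/RLU.  Titrating acceptor
plasmid at fixed donor gives a saturation curve

    y = BRETmax * x / (BRET50 + x)

whose asymptote BRETmax reflects complex structure and whose half-saturation
point BRET50 reflects the relative affinity of the pair.  Compound treatments
are expressed as % inhibition of the vehicle BRET ratio, with a reference
treatment known to abolish the signal (e.g. mevastatin for prenylation-
dependent nanoclustering) providing the maximal-inhibition asymptote for DSS
scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BretWell", "SaturationFit",
    "bret_ratio", "relative_expression", "fit_saturation",
    "select_assay_ad_ratio", "bret_inhibition", "titration_points",
]


@dataclass(frozen=True)
class BretWell:
    """Emission readings for one well.

    ``em515``: acceptor-channel luminescence; ``em410``: donor-channel
    luminescence (RLU, proportional to donor amount); ``rfu``: direct acceptor
    fluorescence (proportional to acceptor amount); ``condition`` is
    ``donor_acceptor`` or ``donor_only``.
    """

    em515: float
    em410: float
    rfu: float = np.nan
    condition: str = "donor_acceptor"
    treatment: str = ""
    time_min: float = np.nan


def bret_ratio(sample: BretWell, donor_only: BretWell) -> float:
    """Background-corrected BRET ratio of a sample well."""
    if sample.em410 <= 0 or donor_only.em410 <= 0:
        raise ZeroDivisionError("donor-channel emission must be positive")
    return sample.em515 / sample.em410 - donor_only.em515 / donor_only.em410


def relative_expression(rfu: float, rlu: float) -> float:
    """Acceptor over donor expression, RFU/RLU."""
    if rlu <= 0:
        raise ZeroDivisionError("RLU must be positive")
    return rfu / rlu


@dataclass
class SaturationFit:
    """Parameters of y = BRETmax * x / (BRET50 + x).

    When the titration shows no curvature (half-saturation far beyond the
    covered expression range) BRETmax and BRET50 are individually unresolved;
    ``resolved`` is False and only ``slope`` (= BRETmax/BRET50, the initial
    slope) is meaningful.
    """

    bret_max: float
    bret_50: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    resolved: bool = True
    slope: float = np.nan


def fit_saturation(rel_expression, ratios) -> SaturationFit:
    """Least-squares saturation fit of BRET ratio vs relative expression.

    Technical replicates should be pre-averaged; points from all biological
    repeats may be pooled into one data set.  At least 5 points are required.
    """
    x = np.asarray(rel_expression, dtype=float)
    y = np.asarray(ratios, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 titration points")
    if np.any(x < 0):
        raise ValueError("relative expression must be non-negative")

    def sat(x_, bmax, b50):
        return bmax * x_ / (b50 + x_)

    p0 = [max(y.max(), 1e-6), max(np.median(x), 1e-6)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(sat, x, y, p0=p0,
                                   bounds=([0.0, 0.0], [np.inf, np.inf]),
                                   maxfev=20000)
    except (RuntimeError, ValueError):
        return SaturationFit(np.nan, np.nan, converged=False, resolved=False)
    bmax, b50 = map(float, popt)
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    stderr = dict(zip(("bret_max", "bret_50"), map(float, perr)))
    if b50 > 10.0 * x.max():
        slope = float(np.sum(x * y) / np.sum(x * x))
        return SaturationFit(np.nan, np.nan, stderr=stderr, resolved=False,
                             slope=slope)
    return SaturationFit(bmax, b50, stderr=stderr, slope=bmax / b50)


def titration_points(wells: pd.DataFrame) -> pd.DataFrame:
    """Reduce a titration well table to (rel_expression, ratio) points.

    ``wells`` needs columns ``condition, em515, em410, rfu`` and optionally
    ``replicate``.  The donor-only background raw ratio is averaged per
    replicate (i.e. per plate) and subtracted from each donor+acceptor well's
    raw ratio; technical replicates of the same expression point are not
    averaged here — pooling across repeats before fitting is the caller's
    choice.
    """
    grpkey = "replicate" if "replicate" in wells.columns else None
    out = []
    for _, grp in (wells.groupby(grpkey) if grpkey else [(None, wells)]):
        donor = grp[grp["condition"] == "donor_only"]
        if donor.empty:
            raise ValueError("titration table has no donor_only background wells")
        bg = float((donor["em515"] / donor["em410"]).mean())
        da = grp[grp["condition"] == "donor_acceptor"]
        out.append(pd.DataFrame({
            "rel_expression": da["rfu"] / da["em410"],
            "ratio": da["em515"] / da["em410"] - bg,
        }))
    return pd.concat(out, ignore_index=True)


def select_assay_ad_ratio(titration: pd.DataFrame, fit: SaturationFit):
    """Pick the acceptor/donor plasmid ratio for compound testing.

    The assay wants the quasi-linear, sub-saturation part of the titration,
    where the BRET ratio still responds proportionally to changes in
    clustering.  Operationally: the tested A/D ratio whose mean relative
    expression lies closest to BRET50/2, ties broken toward the lower ratio
    (lower expression).  If every tested ratio sits beyond saturation
    (x > 3*BRET50) the lowest-expression ratio is returned with a warning.

    ``titration`` needs columns ``ad_ratio`` and ``rel_expression``.
    """
    if not fit.resolved:
        raise ValueError("saturation fit unresolved; cannot select an A/D ratio")
    means = titration.groupby("ad_ratio")["rel_expression"].mean()
    if len(means) < 3:
        raise ValueError("need at least 3 distinct A/D ratios")
    if means.min() > 3.0 * fit.bret_50:
        warnings.warn("all tested A/D ratios are beyond saturation; "
                      "returning the lowest-expression ratio")
        return means.idxmin()
    target = fit.bret_50 / 2.0
    dist = (means - target).abs()
    # stable tie-break toward the lower A/D ratio
    best = dist.min()
    candidates = sorted(dist.index[np.isclose(dist.values, best)])
    return candidates[0]


def bret_inhibition(treated_ratios: dict, vehicle_ratio: float,
                    asymptote_ratio: float | None = None):
    """Convert treated BRET ratios into % inhibition of the vehicle signal.

    ``inhibition_i = 100 * (vehicle - treated_i) / vehicle``.  When an
    asymptote reference (a treatment producing maximal signal loss) is given,
    its inhibition is returned as the asymptote parameter ``a`` for DSS
    scoring of BRET dose responses.

    Returns ``(DataFrame[treatment, value, mode], a)`` with mode
    ``"inhibition"``; ``a`` is None without an asymptote reference.
    """
    if vehicle_ratio <= 0:
        raise ValueError("vehicle BRET ratio must be positive")
    rows = [
        {"treatment": name, "value": 100.0 * (vehicle_ratio - r) / vehicle_ratio,
         "mode": "inhibition"}
        for name, r in treated_ratios.items()
    ]
    a = None
    if asymptote_ratio is not None:
        a = 100.0 * (vehicle_ratio - asymptote_ratio) / vehicle_ratio
    return pd.DataFrame(rows), a
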