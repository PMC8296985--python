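"""Composite drug activity score and compound ranking.

The screen seeks compounds that combine four desiderata: strong activity
against the on-target (KRAS-mutant) spheroid line, selectivity over the
off-target (HRAS-mutant) line, low unspecific 2D toxicity against the
off-target line relative to the on-target line, and high binding affinity.
These are folded into one number:

    score = DSS_target^2 / DSS_offtarget
            * tox_offtarget / tox_target
            * 1 / Kd[uM]

The score is deliberately dimensionally heterogeneous — it is a ranking
heuristic, not a physical quantity.  Kd enters in micromolar so magnitudes
land in a convenient regime; the unit is validated, not assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompositeScoreResult", "composite_score", "rank_compounds"]


@dataclass
class CompositeScoreResult:
    """One compound's assay inputs and composite score."""

    compound: str
    dss_target: float
    dss_offtarget: float
    tox_offtarget: float
    tox_target: float
    kd_uM: float
    score: float
    series: str = ""


def composite_score(
    compound: str,
    dss_target: float,
    dss_offtarget: float,
    tox_offtarget: float,
    tox_target: float,
    kd_uM: float,
    series: str = "",
) -> CompositeScoreResult:
    """Compute the composite drug activity score for one compound.

    DSS inputs are DSS3 scores of the on-/off-target spheroid lines; tox
    inputs are 2D percent toxicities at the single screening dose; kd_uM is
    the binding affinity in micromolar.  Raises on non-positive denominators
    (dss_offtarget, tox_target, kd_uM) — callers assembling score tables
    should exclude such compounds and record the reason.
    """
    for name, v in (("dss_offtarget", dss_offtarget), ("tox_target", tox_target),
                    ("kd_uM", kd_uM)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r} for {compound}")
    score = (dss_target ** 2 / dss_offtarget) * (tox_offtarget / tox_target) / kd_uM
    return CompositeScoreResult(compound, dss_target, dss_offtarget,
                                tox_offtarget, tox_target, kd_uM, score, series)


def rank_compounds(scores, top_n: int | None = 3):
    """Rank scored compounds, optionally keeping the top n per series.

    Ordering is by descending score; ties break toward the lower Kd, then
    lexicographic compound id.  ``top_n=None`` returns the full ranking.
    """
    ordered = sorted(scores, key=lambda s: (-s.score, s.kd_uM, s.compound))
    if top_n is None:
        return ordered
    kept, counts = [], {}
    for s in ordered:
        counts[s.series] = counts.get(s.series, 0) + 1
        if counts[s.series] <= top_n:
            kept.append(s)
    return kept
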