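"""Seeded synthetic data generators for every assay in the pipeline.

Each generator emits a table in exactly the schema the corresponding reader
or fitter consumes, with the statistical structure that assay assumes:

- 4PL dose-response plates with vehicle and kill-control wells;
- FP displacement curves driven by the exact competitive equilibrium;
- covalent time courses decaying with kobs = k2*[I]/(Ki + [I]);
- BRET donor-saturation titrations following the binding-saturation curve,
  with donor-only background wells.

Noise is multiplicative (coefficient of variation ``cv``) plus an additive
floor expressed as a fraction of the signal scale (``additive_frac``),
mirroring plate-reader behaviour where shot noise scales with signal but a
read-noise floor remains.  A fixed seed makes every generator bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dose_response import logistic4
from .fp_binding import FPAssayConfig, bound_probe_zero_inhibitor, solve_competitive_equilibrium

__all__ = [
    "SimulationConfig",
    "gen_dose_response", "gen_fp_displacement", "gen_fp_timecourse",
    "gen_bret_titration", "predict_ic50", "kras_ad_titration",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model and replication for the generators.

    ``cv`` is the multiplicative coefficient of variation (default 2%);
    ``additive_frac`` the additive noise sd as a fraction of the signal scale
    (default 0.2%); ``replicates`` the number of technical replicates.
    Set both noise terms to 0 for exact, noise-free data.
    """

    seed: int = 0
    cv: float = 0.02
    additive_frac: float = 0.002
    replicates: int = 3

    def __post_init__(self):
        if self.cv < 0 or self.additive_frac < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noisy(values, scale, cfg: SimulationConfig, rng) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    out = values * (1.0 + cfg.cv * rng.standard_normal(values.shape))
    out = out + cfg.additive_frac * scale * rng.standard_normal(values.shape)
    return out


def gen_dose_response(
    bottom: float, top: float, hill: float, log10_mid: float,
    cfg: SimulationConfig,
    conc=None,
    vehicle_level: float = 10_000.0,
    kill_level: float = 500.0,
    compound: str = "cmpd",
) -> pd.DataFrame:
    """Raw-signal viability plate from a ground-truth % inhibition 4PL curve.

    Vehicle wells sit at ``vehicle_level`` (100% viability) and kill-control
    wells at ``kill_level`` (0%), so after control normalization the expected
    % inhibition equals the truth curve exactly.  The default dose series is
    10 half-log steps over 0.6-40 uM, a typical covalent-screen window.
    """
    rng = cfg.rng()
    if conc is None:
        conc = np.geomspace(0.6e-6, 40e-6, 10)
    conc = np.asarray(conc, dtype=float)
    inhibition = logistic4(np.log10(conc), bottom, top, hill, log10_mid)
    viability = 100.0 - inhibition
    signal_truth = kill_level + (vehicle_level - kill_level) * viability / 100.0

    rows = []
    w = 0
    for rep in range(1, cfg.replicates + 1):
        for c, s in zip(conc, signal_truth):
            rows.append(("W%03d" % (w := w + 1), compound, c, "treatment", s, rep))
        rows.append(("W%03d" % (w := w + 1), "DMSO", 0.0, "vehicle", vehicle_level, rep))
        rows.append(("W%03d" % (w := w + 1), "benzethonium", 0.0, "kill_control", kill_level, rep))
    df = pd.DataFrame(rows, columns=["well", "compound", "conc", "role", "signal", "replicate"])
    df["signal"] = np.clip(_noisy(df["signal"].to_numpy(), vehicle_level, cfg, rng), 0.0, None)
    return df


def predict_ic50(true_kd: float, config: FPAssayConfig) -> float:
    """Total inhibitor concentration at which half the bound probe is displaced.

    Found by root-finding on the exact competitive equilibrium; serves both
    to centre simulated dilution series and as an oracle for the IC50 fit.
    """
    ep0 = bound_probe_zero_inhibitor(config)

    def half_displacement(i_total):
        return solve_competitive_equilibrium(config, i_total, true_kd).protein_probe - ep0 / 2.0

    hi = max(true_kd, config.protein_total) * 4.0
    while half_displacement(hi) > 0:
        hi *= 10.0
        if hi > 1e3:
            raise RuntimeError("could not bracket the displacement midpoint")
    return brentq(half_displacement, 0.0, hi, xtol=1e-30, rtol=1e-15)


def gen_fp_displacement(
    true_kd: float,
    config: FPAssayConfig,
    cfg: SimulationConfig,
    conc=None,
    r_free: float = 0.05,
    r_bound: float = 0.25,
    compound: str = "cmpd",
) -> pd.DataFrame:
    """FP displacement curve (anisotropy vs total inhibitor) for one compound.

    Anisotropy interpolates linearly in the bound-probe fraction between
    ``r_free`` (displaced) and ``r_bound`` (fully bound probe), computed from
    the exact competitive equilibrium at each dose.  The default dose series
    is threefold dilution (13 points) centred on the predicted IC50, since
    under probe/protein depletion the IC50 can sit orders of magnitude above
    the inhibitor Kd.
    """
    rng = cfg.rng()
    if conc is None:
        conc = predict_ic50(true_kd, config) * 3.0 ** np.arange(-6, 7)
    conc = np.asarray(conc, dtype=float)
    frac = np.array([
        solve_competitive_equilibrium(config, c, true_kd).protein_probe / config.probe_total
        for c in conc
    ])
    r = r_free + (r_bound - r_free) * frac

    rows = []
    for rep in range(1, cfg.replicates + 1):
        noisy = _noisy(r, r_bound, cfg, rng)
        for c, a in zip(conc, noisy):
            rows.append((compound, c, a, rep))
    return pd.DataFrame(rows, columns=["compound", "conc", "anisotropy", "replicate"])


def gen_fp_timecourse(
    true_ki: float,
    true_k2: float,
    cfg: SimulationConfig,
    conc=None,
    times=None,
    signal_initial: float = 0.30,
    signal_plateau: float = 0.20,
    compound: str = "cmpd",
) -> pd.DataFrame:
    """FP time courses at several inhibitor doses under the covalent model.

    Signal at dose [I] decays as one-phase exponential with
    ``kobs = k2*[I]/(Ki + [I])`` from ``signal_initial`` to
    ``signal_plateau``.  Defaults: 7 concentrations, 5-320 uM twofold, and 9
    time points spanning 24 h (dense early sampling, one overnight point),
    the design typical for covalent FP kinetics.  Additive noise scales with
    the decay span.
    """
    rng = cfg.rng()
    if conc is None:
        conc = 5e-6 * 2.0 ** np.arange(7)  # 5 .. 320 uM
    if times is None:
        times = np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 12.0, 24.0])
    conc = np.asarray(conc, dtype=float)
    times = np.asarray(times, dtype=float)
    span = signal_initial - signal_plateau

    rows = []
    for rep in range(1, cfg.replicates + 1):
        for c in conc:
            kobs = true_k2 * c / (true_ki + c)
            y = signal_plateau + span * np.exp(-kobs * times)
            y = _noisy(y, span, cfg, rng)
            for t, s in zip(times, y):
                rows.append((compound, c, t, s, rep))
    return pd.DataFrame(rows, columns=["compound", "conc", "time_h", "signal", "replicate"])


def kras_ad_titration(points_per_ratio: int = 5) -> pd.DataFrame:
    """Synthetic K-RasG12V-style A/D plasmid titration (noise-free stand-in).

    Emulates a nanoclustering-BRET plasmid titration over acceptor/donor
    ratios 1/1 .. 8/1 with saturation parameters typical of an oncogenic
    K-Ras BRET pair (BRETmax 0.35, BRET50 1.0): doubling the plasmid ratio
    doubles the mean relative expression, placing the 4/1 ratio at the
    half-BRET50, quasi-linear working point.  Returns tidy points with
    columns ``ad_ratio, rel_expression, ratio``.
    """
    bmax, b50 = 0.35, 1.0
    mean_x = {1: 0.125, 2: 0.25, 4: 0.5, 8: 1.0}
    rows = []
    spread = np.linspace(0.85, 1.15, points_per_ratio)
    for ad, mx in mean_x.items():
        for s in spread:
            x = mx * s
            rows.append((ad, x, bmax * x / (b50 + x)))
    return pd.DataFrame(rows, columns=["ad_ratio", "rel_expression", "ratio"])


def gen_bret_titration(
    true_bret_max: float,
    true_bret_50: float,
    cfg: SimulationConfig,
    n_points: int = 12,
    rlu: float = 1e5,
    background: float = 0.08,
    n_donor_only: int = 3,
) -> pd.DataFrame:
    """Donor-saturation titration wells plus donor-only background wells.

    Relative expression spans 0.05x to 4x BRET50 geometrically (acceptor
    plasmid titrated up at fixed donor).  The acceptor-channel emission
    carries the saturation-curve signal on top of the donor bleed-through
    background; the donor channel (RLU) is held at ``rlu``.  Noise enters the
    acceptor channel and the RFU multiplicatively.
    """
    rng = cfg.rng()
    x = np.geomspace(0.05 * true_bret_50, 4.0 * true_bret_50, n_points)
    rows = []
    w = 0
    for rep in range(1, cfg.replicates + 1):
        ratio = true_bret_max * x / (true_bret_50 + x)
        em515 = _noisy((background + ratio) * rlu, rlu, cfg, rng)
        rfu = _noisy(x * rlu, rlu, cfg, rng)
        for xi, e515, f in zip(x, em515, rfu):
            rows.append(("W%03d" % (w := w + 1), "donor_acceptor", "vehicle",
                         e515, rlu, f, rep))
        for _ in range(n_donor_only):
            e515 = float(_noisy(np.array([background * rlu]), rlu, cfg, rng)[0])
            rows.append(("W%03d" % (w := w + 1), "donor_only", "vehicle",
                         e515, rlu, 0.0, rep))
    return pd.DataFrame(rows, columns=["well", "condition", "treatment",
                                       "em515", "em410", "rfu", "replicate"])
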