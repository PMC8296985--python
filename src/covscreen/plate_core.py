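"""Plate-reader table I/O and control-based percent normalization.

Raw plate data arrive as tidy long-format tables, one row per well, carrying a
raw fluorescence or luminescence ``signal`` plus annotations (compound,
concentration, control role, channel, optional time, replicate).  Every
downstream stage of the pipeline consumes percent responses normalized against
on-plate controls:

- *viability / sphere formation*: vehicle wells anchor 100%, a kill control
  (e.g. 100 uM benzethonium chloride, which kills all cells) anchors 0%;
- *toxicity*: vehicle wells anchor 0%, a maximum-lysis control (when present)
  anchors 100%;
- *inhibition*: the complement of viability, ``100 - viability``.

Normalization is affine and therefore order-preserving within a plate.
Out-of-range percentages produced by noise (e.g. 104% viability) are retained
unclamped so that downstream curve fits see unbiased data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ROLES",
    "PlateValidationError",
    "DegenerateControlsError",
    "read_plate_table",
    "validate_plate",
    "normalize_viability",
    "normalize_toxicity",
    "percent_inhibition",
    "average_replicates",
]

#: Recognised control/treatment roles for a well.
ROLES = frozenset({
    "treatment", "vehicle", "kill_control", "asymptote_control",
    "donor_only", "blank",
})

#: Multipliers converting a declared concentration unit to molar.
_UNIT_TO_MOLAR = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
    "nM": 1e-9, "pM": 1e-12,
}

REQUIRED_COLUMNS = ("well", "compound", "conc", "role", "signal")


class PlateValidationError(ValueError):
    """Raised when a plate table violates the input contract."""


class DegenerateControlsError(ValueError):
    """Raised when control wells cannot anchor a normalization scale."""


def read_plate_table(path: str | Path, config: str | Path | dict | None = None) -> pd.DataFrame:
    """Read and validate a tidy long-format plate CSV.

    Parameters
    ----------
    path:
        CSV with columns ``well, compound, conc, role, signal`` and optionally
        ``channel, time_h, replicate, conc_unit``.
    config:
        Mapping (or path to a YAML file) with optional keys:

        - ``conc_unit``: unit of the ``conc`` column (default ``"M"``);
          concentrations are stored internally in molar.
        - ``roles``: extra allowed role labels beyond :data:`ROLES`.

    Returns
    -------
    pandas.DataFrame
        Validated table with ``conc`` in molar and a ``replicate`` column
        (defaulting to 1 when absent).
    """
    path = Path(path)
    if not path.exists():
        raise PlateValidationError(f"plate file not found: {path}")
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    config = dict(config or {})

    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PlateValidationError(f"missing required column(s): {', '.join(missing)}")

    unit = str(config.get("conc_unit", "M"))
    if unit not in _UNIT_TO_MOLAR:
        raise PlateValidationError(f"unknown concentration unit: {unit!r}")
    df = df.copy()
    df["conc"] = pd.to_numeric(df["conc"], errors="coerce") * _UNIT_TO_MOLAR[unit]
    if "replicate" not in df.columns:
        df["replicate"] = 1

    allowed = ROLES | set(config.get("roles", ()))
    validate_plate(df, allowed_roles=allowed)
    return df


def validate_plate(df: pd.DataFrame, allowed_roles: frozenset[str] | set[str] = ROLES) -> None:
    """Check the plate-table invariants, naming the first offending row."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise PlateValidationError(f"missing required column(s): {col}")

    signal = pd.to_numeric(df["signal"], errors="coerce")
    bad = signal.isna() | ~np.isfinite(signal) | (signal < 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise PlateValidationError(
            f"row {i} (well {df['well'].iloc[i]!r}): signal must be finite and non-negative, "
            f"got {df['signal'].iloc[i]!r}"
        )

    unknown = ~df["role"].isin(list(allowed_roles))
    if unknown.any():
        i = int(np.flatnonzero(unknown.to_numpy())[0])
        raise PlateValidationError(
            f"row {i} (well {df['well'].iloc[i]!r}): unknown role {df['role'].iloc[i]!r}"
        )

    conc = pd.to_numeric(df["conc"], errors="coerce")
    bad_conc = (df["role"] == "treatment") & ~(conc > 0)
    if bad_conc.any():
        i = int(np.flatnonzero(bad_conc.to_numpy())[0])
        raise PlateValidationError(
            f"row {i} (well {df['well'].iloc[i]!r}): treatment wells need concentration > 0"
        )


def _control_mean(plate: pd.DataFrame, role: str) -> float | None:
    wells = plate.loc[plate["role"] == role, "signal"]
    if len(wells) == 0:
        return None
    return float(wells.mean())


def normalize_viability(plate: pd.DataFrame, mode: str = "viability") -> pd.DataFrame:
    """Rescale raw signals to percent viability (or sphere formation).

    ``percent = 100 * (signal - mean_kill) / (mean_vehicle - mean_kill)``.
    Vehicle wells map to 100% and kill-control wells to 0% by construction.
    When the plate carries no kill control, a zero-signal floor anchors 0%.

    Returns a tidy frame with columns
    ``well, compound, conc, replicate, role, value, mode``.
    """
    if mode not in ("viability", "sphere_formation"):
        raise ValueError(f"mode must be viability or sphere_formation, got {mode!r}")
    mean_vehicle = _control_mean(plate, "vehicle")
    if mean_vehicle is None:
        raise DegenerateControlsError("no vehicle wells on plate")
    mean_kill = _control_mean(plate, "kill_control")
    if mean_kill is None:
        mean_kill = 0.0
    if mean_vehicle <= mean_kill:
        raise DegenerateControlsError(
            f"vehicle mean ({mean_vehicle:g}) must exceed kill-control mean ({mean_kill:g})"
        )
    out = plate.loc[:, ["well", "compound", "conc", "replicate", "role"]].copy()
    out["value"] = 100.0 * (plate["signal"] - mean_kill) / (mean_vehicle - mean_kill)
    out["mode"] = mode
    return out


def normalize_toxicity(plate: pd.DataFrame) -> pd.DataFrame:
    """Rescale raw signals to percent toxicity (vehicle = 0%).

    With a maximum-lysis control (role ``kill_control``) present the scale is
    anchored so that control maps to 100% toxicity.  Without one, signals are
    baseline-subtracted and rescaled by the plate maximum, so the most toxic
    well on the plate reads 100%.
    """
    mean_vehicle = _control_mean(plate, "vehicle")
    if mean_vehicle is None:
        raise DegenerateControlsError("no vehicle wells on plate")
    mean_max = _control_mean(plate, "kill_control")
    if mean_max is None:
        mean_max = float(plate["signal"].max())
    if mean_max <= mean_vehicle:
        raise DegenerateControlsError(
            f"max-lysis anchor ({mean_max:g}) must exceed vehicle mean ({mean_vehicle:g})"
        )
    out = plate.loc[:, ["well", "compound", "conc", "replicate", "role"]].copy()
    out["value"] = 100.0 * (plate["signal"] - mean_vehicle) / (mean_max - mean_vehicle)
    out["mode"] = "toxicity"
    return out


def percent_inhibition(resp: pd.DataFrame) -> pd.DataFrame:
    """Convert percent viability/sphere-formation to percent inhibition.

    ``inhibition = 100 - viability`` per well.  Applying the operation to an
    inhibition table converts back to viability, so the transform is an
    involution on values.
    """
    modes = set(resp["mode"].unique())
    flip = {"viability": "inhibition", "sphere_formation": "inhibition",
            "inhibition": "viability"}
    bad = modes - set(flip)
    if bad:
        raise ValueError(f"cannot convert mode(s) {sorted(bad)} to % inhibition")
    out = resp.copy()
    out["value"] = 100.0 - out["value"]
    out["mode"] = out["mode"].map(flip)
    return out


def average_replicates(resp: pd.DataFrame) -> pd.DataFrame:
    """Average normalized responses over replicates, per compound and dose."""
    keys = [c for c in ("compound", "conc", "mode", "role") if c in resp.columns]
    return resp.groupby(keys, as_index=False)["value"].mean()
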