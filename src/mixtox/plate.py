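"""Dual-wavelength absorbance plates -> percent cell viability.

The resazurin (alamarBlue) readout quantifies metabolic activity by the
absorbance difference A570 - A600; medium-only blank wells supply the
background at both wavelengths and vehicle-control wells define 100%
viability.  For a treated well

    viability = [(A570_t - A570_b) - (A600_t - A600_b)]
                / mean_controls[(A570_c - A570_b) - (A600_c - A600_b)] * 100

where blank readings are the per-plate mean over all blank wells at each
wavelength (symmetric with the control averaging; identical to a single
blank read when only one blank well exists).  Blanks and controls are always
matched within a plate, never pooled across plates, because every plate
carries its own solvent control.

Individual-well viabilities may be negative or exceed 100; they are
deliberately not clipped so downstream statistics see unbiased noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PLATE_COLUMNS",
    "PlateError",
    "MissingWellsError",
    "DegeneratePlateError",
    "validate_plate",
    "compute_viability",
    "ViabilityNormalizer",
]

#: required columns of a long-format plate table
PLATE_COLUMNS = ("plate_id", "well", "role", "condition_id", "a570", "a600")

_ROLES = frozenset({"treated", "control", "blank"})


class PlateError(ValueError):
    """Base class for plate-validation failures."""


class MissingWellsError(PlateError):
    """A plate lacks blank or control wells, so viability is undefined."""


class DegeneratePlateError(PlateError):
    """The control denominator of a plate is zero or negative."""


def validate_plate(readings: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format plate table and return it with clean dtypes.

    Parameters
    ----------
    readings
        DataFrame with columns ``plate_id, well, role, condition_id, a570,
        a600``; one row per well.  ``role`` is one of ``treated``,
        ``control``, ``blank``.

    Raises
    ------
    MissingWellsError
        If any plate has no blank or no control well.
    PlateError
        On malformed roles, non-finite or negative absorbances, or treated
        wells without a condition_id.
    """
    missing = [c for c in PLATE_COLUMNS if c not in readings.columns]
    if missing:
        raise PlateError(f"plate table missing columns: {missing}")
    df = readings.loc[:, list(PLATE_COLUMNS)].copy()
    df["role"] = df["role"].astype(str).str.strip().str.lower()
    bad_roles = set(df["role"]) - _ROLES
    if bad_roles:
        raise PlateError(f"unknown well roles: {sorted(bad_roles)}")
    for col in ("a570", "a600"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise PlateError(f"non-finite values in {col}")
        if np.any(vals < 0):
            raise PlateError(f"negative absorbance in {col}")
    treated = df["role"] == "treated"
    cond = df["condition_id"].astype("string")
    if (treated & (cond.isna() | (cond.str.len() == 0))).any():
        raise PlateError("treated wells must carry a condition_id")
    for plate_id, grp in df.groupby("plate_id", sort=False):
        roles = set(grp["role"])
        absent = {"blank", "control"} - roles
        if absent:
            raise MissingWellsError(
                f"plate {plate_id!r} has no {'/'.join(sorted(absent))} wells; "
                "viability is undefined"
            )
    return df


def compute_viability(
    readings: pd.DataFrame, *, include_controls: bool = False
) -> pd.DataFrame:
    """Convert raw well absorbances to percent viability, per plate.

    Parameters
    ----------
    readings
        Long-format plate table (see :func:`validate_plate`).  May contain
        several plates; blanks and controls are matched within ``plate_id``.
    include_controls
        Diagnostic mode: also emit one row per control well (their mean is
        exactly 100 by construction).

    Returns
    -------
    DataFrame with columns ``plate_id, condition_id, well, replicate,
    viability_pct`` — one row per treated well (replicate indices count
    within each condition on each plate).  Blank wells produce no rows.

    Raises
    ------
    DegeneratePlateError
        If a plate's mean control signal is zero or negative.
    """
    df = validate_plate(readings)
    out: list[pd.DataFrame] = []
    for plate_id, grp in df.groupby("plate_id", sort=False):
        blanks = grp[grp["role"] == "blank"]
        controls = grp[grp["role"] == "control"]
        b570 = blanks["a570"].mean()
        b600 = blanks["a600"].mean()
        signal = (grp["a570"] - b570) - (grp["a600"] - b600)
        denom = signal[controls.index].mean()
        if denom <= 0:
            raise DegeneratePlateError(
                f"plate {plate_id!r}: mean control signal {denom:.4g} <= 0"
            )
        keep = grp["role"] == "treated"
        if include_controls:
            keep = keep | (grp["role"] == "control")
        sub = grp[keep].copy()
        sub["viability_pct"] = signal[sub.index] / denom * 100.0
        sub.loc[sub["role"] == "control", "condition_id"] = "__control__"
        sub["replicate"] = sub.groupby("condition_id").cumcount() + 1
        out.append(
            sub[["plate_id", "condition_id", "well", "replicate", "viability_pct"]]
        )
    return pd.concat(out, ignore_index=True)


class ViabilityNormalizer(TransformerMixin, BaseEstimator):
    """Stateless transformer wrapping :func:`compute_viability`.

    Lets plate normalization sit at the head of an sklearn pipeline: the
    input is a long-format plate table and the output a viability table.
    Blank/control means are computed from the transformed table itself
    (normalization is within-plate by design), so ``fit`` only validates.

    Parameters
    ----------
    include_controls
        If True, control wells are emitted too (diagnostic mode).
    """

    def __init__(self, include_controls: bool = False):
        self.include_controls = include_controls

    def fit(self, X: pd.DataFrame, y=None) -> "ViabilityNormalizer":
        validate_plate(X)
        self.n_plates_ = X["plate_id"].nunique()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return compute_viability(X, include_controls=self.include_controls)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            ["plate_id", "condition_id", "well", "replicate", "viability_pct"]
        )
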