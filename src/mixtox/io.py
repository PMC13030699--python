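"""Delimited-text readers and writers for the pipeline's table formats.

All tables are plain comma- or tab-separated text with headers; the
delimiter is sniffed.  Formats:

* plate table (long): ``plate_id, well, role, condition_id, a570, a600``
* plate map (grid dialect): three aligned row x column grids — condition
  ids (with the reserved words ``blank`` and ``control``), A570 readings,
  A600 readings — normalized to the long format
* dose-viability table: ``compound, exposure_h, dose_mM, viability_pct``
  (one row per replicate well)
* mixture design: ``mixture_id, compound, dose_mM, fraction_of_ic50``
* observed mixture replicates: ``mixture_id, replicate, viability_pct``
* curve report (IC50 summary): ``compound, exposure_h, ic50_mM,
  ci_low_mM, ci_high_mM, r2, converged, n_points``
* interaction report: ``exposure_h, mixture, observed_pct, predicted_pct,
  interaction, p_value, model``

Report writers round to 3 decimals for display parity with the published
tables; machine-precision values stay available on the in-memory frames.
"""

from __future__ import annotations

from pathlib import Path
import numpy as np
import pandas as pd

from .dose_response import DoseResponseDataset
from .mixture import MixtureComponent, MixtureDesign
from .plate import validate_plate

__all__ = [
    "read_table",
    "read_plate_table",
    "read_plate_map",
    "read_dose_response_table",
    "read_mixture_designs",
    "read_observed_replicates",
    "write_viability_table",
    "write_curve_report",
    "write_interaction_report",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, sniffing comma vs tab."""
    return pd.read_csv(path, sep=None, engine="python")


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format plate table."""
    return validate_plate(read_table(path))


def read_plate_map(
    map_path: str | Path,
    a570_path: str | Path,
    a600_path: str | Path,
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """Normalize the grid plate-map dialect to the long plate format.

    Each file is a grid whose first column holds plate row labels (A-H)
    and whose header row holds column numbers.  Cells of the map grid are
    condition ids, the reserved words ``blank`` / ``control``, or empty
    for unused wells.
    """
    cond = pd.read_csv(map_path, sep=None, engine="python", index_col=0, dtype=str)
    a570 = pd.read_csv(a570_path, sep=None, engine="python", index_col=0)
    a600 = pd.read_csv(a600_path, sep=None, engine="python", index_col=0)
    if not (cond.shape == a570.shape == a600.shape):
        raise ValueError(
            f"grid shapes differ: map {cond.shape}, "
            f"a570 {a570.shape}, a600 {a600.shape}"
        )
    rows = []
    for r in cond.index:
        for c in cond.columns:
            cell = cond.loc[r, c]
            if pd.isna(cell) or not str(cell).strip():
                continue
            cell = str(cell).strip()
            role = cell.lower() if cell.lower() in ("blank", "control") else "treated"
            rows.append(dict(
                plate_id=plate_id,
                well=f"{r}{c}",
                role=role,
                condition_id=None if role != "treated" else cell,
                a570=float(a570.loc[r, c]),
                a600=float(a600.loc[r, c]),
            ))
    return validate_plate(pd.DataFrame(rows))


def read_dose_response_table(path: str | Path) -> dict[tuple[str, float], DoseResponseDataset]:
    """Read a replicate-level dose-viability table into datasets.

    Returns a dict keyed by ``(compound, exposure_h)``.
    """
    df = read_table(path)
    required = {"compound", "exposure_h", "dose_mM", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    out = {}
    for (compound, exposure_h), grp in df.groupby(["compound", "exposure_h"]):
        out[(str(compound), float(exposure_h))] = DoseResponseDataset(
            compound=str(compound),
            exposure_h=float(exposure_h),
            dose_mM=grp["dose_mM"].to_numpy(dtype=float),
            viability_pct=grp["viability_pct"].to_numpy(dtype=float),
        )
    return out


def read_mixture_designs(
    path: str | Path, exposure_h: float = 24.0
) -> dict[str, MixtureDesign]:
    """Read a mixture-design table into designs keyed by mixture_id."""
    df = read_table(path)
    required = {"mixture_id", "compound", "dose_mM", "fraction_of_ic50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    out = {}
    for mixture_id, grp in df.groupby("mixture_id", sort=False):
        out[str(mixture_id)] = MixtureDesign(
            components=tuple(
                MixtureComponent(
                    compound=str(row.compound),
                    concentration_mM=float(row.dose_mM),
                    fraction_of_ic50=float(row.fraction_of_ic50),
                )
                for row in grp.itertuples()
            ),
            exposure_h=exposure_h,
        )
    return out


def read_observed_replicates(path: str | Path) -> dict[str, np.ndarray]:
    """Read observed mixture replicate viabilities keyed by mixture_id."""
    df = read_table(path)
    required = {"mixture_id", "replicate", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observed table missing columns: {sorted(missing)}")
    return {
        str(mid): grp.sort_values("replicate")["viability_pct"].to_numpy(dtype=float)
        for mid, grp in df.groupby("mixture_id", sort=False)
    }


def _write(df: pd.DataFrame, path: str | Path, decimals: int | None) -> None:
    if decimals is not None:
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(lambda x: f"{x:.{decimals}f}")
    df.to_csv(path, index=False)


def write_viability_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format viability table."""
    _write(table, path, decimals=None)


def write_curve_report(
    report: pd.DataFrame, path: str | Path, decimals: int | None = 3
) -> None:
    """Write the IC50 summary report (3 decimals by default)."""
    _write(report, path, decimals)


def write_interaction_report(
    report: pd.DataFrame, path: str | Path, decimals: int | None = 3
) -> None:
    """Write the mixture-interaction report (3 decimals by default)."""
    _write(report, path, decimals)
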