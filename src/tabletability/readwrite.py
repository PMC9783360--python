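"""CSV schemas and validated readers/writers.

All tabular I/O is UTF-8 CSV with a mandatory header row and dot decimal
separator.  ``materials.csv`` carries one row per material × form with the
19 physical descriptors; ``tablets.csv`` one row per tablet.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mechanics import MaterialDensity
from .multivariate import PROPERTY_COLUMNS

MATERIALS_KEY_COLUMNS = ["material_id", "form", "material_class"]
MATERIALS_COLUMNS = MATERIALS_KEY_COLUMNS + PROPERTY_COLUMNS
TABLETS_COLUMNS = [
    "material_id",
    "form",
    "applied_force_kN",
    "mass_g",
    "diameter_mm",
    "thickness_mm",
    "crush_force_N",
]
VALID_FORMS = ("powder", "granule")


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _check_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = frame.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: non-numeric value {out[col].iloc[row]!r} in column "
                f"{col!r}, row {row + 2}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise SchemaError(f"{path}: empty cell in column {col!r}, row {row + 2}")
        out[col] = converted
    return out


def read_materials(path) -> pd.DataFrame:
    """Read and validate the material-property table.

    Errors on missing columns, non-numeric cells and duplicate
    (material_id, form) keys; warns on rows violating the density ordering
    Da <= Dc <= Dt (Hausner-ratio invariant).
    """
    frame = pd.read_csv(path)
    _check_columns(frame, MATERIALS_COLUMNS, path)
    frame = _check_numeric(frame, PROPERTY_COLUMNS, path)
    bad_form = ~frame["form"].isin(VALID_FORMS)
    if bad_form.any():
        raise SchemaError(
            f"{path}: invalid form value(s) {sorted(frame.loc[bad_form, 'form'].unique())}"
        )
    dup = frame.duplicated(subset=["material_id", "form"])
    if dup.any():
        key = frame.loc[dup, ["material_id", "form"]].iloc[0].tolist()
        raise SchemaError(f"{path}: duplicate (material_id, form) key {key}")
    for _, row in frame.iterrows():
        density = MaterialDensity(
            true_density=row["Dt_g_cm3"],
            bulk_density=row["Da_g_mL"],
            tapped_density=row["Dc_g_mL"],
        )
        for problem in density.validate():
            warnings.warn(
                f"{path}: {row['material_id']}/{row['form']}: {problem}", stacklevel=2
            )
    return frame


def read_tablets(path) -> pd.DataFrame:
    """Read and validate the raw tablet-measurement table."""
    frame = pd.read_csv(path)
    _check_columns(frame, TABLETS_COLUMNS, path)
    if len(frame) == 0:
        raise SchemaError(f"{path}: tablet table is empty")
    numeric = [c for c in TABLETS_COLUMNS if c not in ("material_id", "form")]
    frame = _check_numeric(frame, numeric, path)
    bad_form = ~frame["form"].isin(VALID_FORMS)
    if bad_form.any():
        raise SchemaError(
            f"{path}: invalid form value(s) {sorted(frame.loc[bad_form, 'form'].unique())}"
        )
    for col in ("applied_force_kN", "mass_g", "diameter_mm", "thickness_mm"):
        if (frame[col] <= 0).any():
            row = int(np.flatnonzero(frame[col] <= 0)[0])
            raise SchemaError(f"{path}: non-positive {col} in row {row + 2}")
    if (frame["crush_force_N"] < 0).any():
        raise SchemaError(f"{path}: negative crush force")
    return frame


def densities_from_materials(materials: pd.DataFrame) -> dict:
    """(material_id, form) -> MaterialDensity mapping for the mechanics stage."""
    return {
        (row["material_id"], row["form"]): MaterialDensity(
            true_density=row["Dt_g_cm3"],
            bulk_density=row["Da_g_mL"],
            tapped_density=row["Dc_g_mL"],
        )
        for _, row in materials.iterrows()
    }


def write_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
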