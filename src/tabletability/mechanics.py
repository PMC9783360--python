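"""Out-of-die tablet mechanics: pressure, tensile strength, porosity.

Unit conventions are fixed package-wide and all conversions live here:
applied force in kN, crush force in N, lengths in mm, mass in g,
densities in g·cm⁻³ (≡ g·mL⁻¹), pressure and tensile strength in MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "MaterialDensity",
    "PorosityResult",
    "compaction_pressure",
    "punch_force",
    "tensile_strength",
    "tablet_porosity",
    "process_tablets",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class MaterialDensity:
    """Bulk (Da), tapped (Dc) and true (Dt) density of a material, g·cm⁻³.

    A physically sensible powder satisfies 0 < Da <= Dc <= Dt; violations
    are reported by :meth:`validate` as warnings rather than errors because
    measured SeDeM tables occasionally contain them.
    """

    true_density: float
    bulk_density: float
    tapped_density: float

    def validate(self) -> list[str]:
        problems = []
        if not self.bulk_density > 0:
            problems.append(f"bulk density must be positive, got {self.bulk_density}")
        if self.bulk_density > self.tapped_density:
            problems.append(
                f"bulk density {self.bulk_density} exceeds tapped density "
                f"{self.tapped_density} (Hausner ratio < 1)"
            )
        if self.tapped_density > self.true_density:
            problems.append(
                f"tapped density {self.tapped_density} exceeds true density "
                f"{self.true_density}"
            )
        return problems


class PorosityResult(NamedTuple):
    apparent_density: np.ndarray | float  # g·cm⁻³
    porosity: np.ndarray | float  # dimensionless
    solid_fraction: np.ndarray | float  # dimensionless, SF = 1 − ε exactly
    suspect: np.ndarray | bool  # ρapp > ρt beyond tolerance


def _check_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(arr > 0):
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def compaction_pressure(force_kn, punch_diameter_mm=10.0):
    """Compaction pressure in MPa from punch force (kN) and punch diameter (mm).

    P = 1000·F / (π·(d/2)²); for the 10 mm flat-faced punch used throughout,
    1 kN corresponds to 12.732 MPa.
    """
    _check_positive(force_kn=force_kn, punch_diameter_mm=punch_diameter_mm)
    force_kn = np.asarray(force_kn, dtype=float)
    area_mm2 = np.pi * (np.asarray(punch_diameter_mm, dtype=float) / 2.0) ** 2
    out = 1000.0 * force_kn / area_mm2
    return out.item() if out.ndim == 0 else out


def punch_force(pressure_mpa, punch_diameter_mm=10.0):
    """Punch force in kN producing a given compaction pressure (inverse map)."""
    _check_positive(pressure_mpa=pressure_mpa, punch_diameter_mm=punch_diameter_mm)
    pressure_mpa = np.asarray(pressure_mpa, dtype=float)
    area_mm2 = np.pi * (np.asarray(punch_diameter_mm, dtype=float) / 2.0) ** 2
    out = pressure_mpa * area_mm2 / 1000.0
    return out.item() if out.ndim == 0 else out


def tensile_strength(crush_force_n, diameter_mm, thickness_mm):
    """Diametrical tensile strength TS = 2F/(π·D·H) in MPa.

    F is the crush force (N), D the tablet diameter (mm) and H the tablet
    thickness (mm). F = 0 gives TS = 0.
    """
    _check_positive(diameter_mm=diameter_mm, thickness_mm=thickness_mm)
    crush = np.asarray(crush_force_n, dtype=float)
    if np.any(crush < 0):
        raise ValueError(f"crush force must be non-negative, got {crush_force_n!r}")
    out = 2.0 * crush / (np.pi * np.asarray(diameter_mm, float) * np.asarray(thickness_mm, float))
    return out.item() if out.ndim == 0 else out


def tablet_porosity(mass_g, diameter_mm, thickness_mm, true_density, dense_tolerance=0.02):
    """Apparent density, porosity and solid fraction of an out-of-die tablet.

    ρapp = m / (π·(D/2)²·H) converted to g·cm⁻³; ε = 1 − ρapp/ρt;
    SF = 1 − ε exactly.  Tablets denser than the true density by more than
    ``dense_tolerance`` (relative) are flagged suspect with a warning but
    are kept — downstream fits may exclude them via configuration.
    """
    _check_positive(
        mass_g=mass_g,
        diameter_mm=diameter_mm,
        thickness_mm=thickness_mm,
        true_density=true_density,
    )
    mass_g = np.asarray(mass_g, dtype=float)
    volume_mm3 = np.pi * (np.asarray(diameter_mm, float) / 2.0) ** 2 * np.asarray(thickness_mm, float)
    rho_app = 1000.0 * mass_g / volume_mm3  # g/mm³ → g/cm³
    porosity = 1.0 - rho_app / np.asarray(true_density, dtype=float)
    solid_fraction = 1.0 - porosity
    suspect = rho_app > np.asarray(true_density, float) * (1.0 + dense_tolerance)
    if np.any(suspect):
        warnings.warn(
            f"{int(np.sum(suspect))} tablet(s) denser than the true density "
            f"beyond tolerance {dense_tolerance:g}; flagged as suspect",
            stacklevel=2,
        )
    if rho_app.ndim == 0:
        return PorosityResult(
            rho_app.item(), float(porosity), float(solid_fraction), bool(suspect)
        )
    return PorosityResult(rho_app, porosity, solid_fraction, suspect)


def process_tablets(tablets, densities, punch_diameter_mm=10.0, dense_tolerance=0.02):
    """Reduce raw per-tablet measurements to pressure/TS/porosity states.

    Parameters
    ----------
    tablets : pandas.DataFrame
        One row per tablet with columns ``material_id``, ``form``,
        ``applied_force_kN``, ``mass_g``, ``diameter_mm``, ``thickness_mm``,
        ``crush_force_N``.
    densities : mapping
        ``(material_id, form) -> MaterialDensity``.

    Returns a copy of ``tablets`` with added columns ``pressure_MPa``,
    ``tensile_strength_MPa``, ``apparent_density_g_cm3``, ``porosity``,
    ``solid_fraction`` and boolean ``suspect``.
    """
    out = tablets.copy()
    out["pressure_MPa"] = compaction_pressure(
        out["applied_force_kN"].to_numpy(), punch_diameter_mm
    )
    out["tensile_strength_MPa"] = tensile_strength(
        out["crush_force_N"].to_numpy(),
        out["diameter_mm"].to_numpy(),
        out["thickness_mm"].to_numpy(),
    )
    true_density = np.array(
        [densities[(m, f)].true_density for m, f in zip(out["material_id"], out["form"])]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, eps, sf, suspect = tablet_porosity(
            out["mass_g"].to_numpy(),
            out["diameter_mm"].to_numpy(),
            out["thickness_mm"].to_numpy(),
            true_density,
            dense_tolerance=dense_tolerance,
        )
    out["apparent_density_g_cm3"] = rho
    out["porosity"] = eps
    out["solid_fraction"] = sf
    out["suspect"] = suspect
    return out


def aggregate_replicates(states, rule="mean"):
    """Average replicate tablets compressed at the same nominal force.

    Groups by (material_id, form, applied_force_kN) and aggregates the
    derived quantities by ``mean`` (default) or ``median``.
    """
    if rule not in ("mean", "median"):
        raise ValueError(f"aggregation rule must be 'mean' or 'median', got {rule!r}")
    value_cols = [
        "pressure_MPa",
        "tensile_strength_MPa",
        "apparent_density_g_cm3",
        "porosity",
        "solid_fraction",
    ]
    grouped = (
        states.groupby(["material_id", "form", "applied_force_kN"], sort=True)[value_cols]
        .agg(rule)
        .reset_index()
    )
    n_rep = (
        states.groupby(["material_id", "form", "applied_force_kN"], sort=True)
        .size()
        .rename("n_replicates")
        .reset_index()
    )
    return grouped.merge(n_rep, on=["material_id", "form", "applied_force_kN"])
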