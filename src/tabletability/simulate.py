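"""Synthetic material library with known ground truth.

Emulates a 29-material library (17 excipient-like, 12 natural-product-like
materials, each as an ungranulated powder and a wet-granulated granule):

* porosity–pressure behaviour generated from the Gurnham form
  ε(P) = −(1/K)·ln(P/P0), parameterised by the porosity at the window
  edges so every curve is physical on 10–140 MPa;
* tabletability generated from the power law TS = d·P^g, with the
  powder/granule pair constructed to realise a planted relative change of
  tabletability (CoTr) against the library-wide AUC envelope;
* a correlated 19-column physical-property block from a three-factor
  latent model (particle size/flow, densification, hygroscopicity) in
  which particle size anticorrelates with flow time, inter-particle
  porosity and the cohesion index, and natural-product rows are finer and
  more hygroscopic than excipient rows;
* multiplicative log-normal measurement noise on porosity and tensile
  strength (default 1% relative) so both stay positive.

The default roster plants the category and type book-keeping of a real
granulation study: powder CBCS categories {1: 7, 2A: 15, 2B: 6, 2C: 1},
granule categories {1: 3, 2A: 13, 2B: 10, 2C: 3} (ten downgrades), and
TCCS types {Ia: 5, Ib: 7, II: 14, III: 3}.  All randomness flows from a
single master seed through named child streams, so regeneration from the
same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .change import DEFAULT_AUC_WINDOW, LibraryEnvelope, auc_power, library_envelope
from .classify import CBCSCategory, classify_cbcs
from .mechanics import punch_force
from .multivariate import PROPERTY_COLUMNS

__all__ = [
    "FormTruth",
    "GroundTruthMaterial",
    "SyntheticLibrary",
    "DEFAULT_PRESSURES",
    "ROSTER",
    "make_material",
    "generate_curves",
    "make_pair_with_cotr",
    "make_property_block",
    "make_library",
    "library_tables",
]

#: Six compaction pressures (MPa) spanning the 10–140 MPa tableting range,
#: three of them inside the 0–50 MPa Shapiro window.
DEFAULT_PRESSURES = (10.0, 25.0, 40.0, 70.0, 105.0, 140.0)

_LN14 = math.log(140.0 / 10.0)


@dataclass
class RosterEntry:
    material_id: str
    material_class: str  # "excipient" | "natural_product"
    archetype: str  # "plastic" | "brittle" | "elastic"
    powder_category: str
    granule_category: str
    tccs_type: str
    auc_p_range: tuple[float, float]  # MPa²
    cotr_range: tuple[float, float]  # percent


# Planted roster: AUC ranges and CoTr bands are chosen so every planted
# (powder category, granule category, TCCS type) triple is geometrically
# feasible against the resulting library envelope (see docs/methods.md).
ROSTER: tuple[RosterEntry, ...] = (
    RosterEntry("E01", "excipient", "plastic", "1", "2A", "Ia", (1250, 1400), (-52, -20)),
    RosterEntry("E02", "excipient", "plastic", "1", "1", "Ia", (1150, 1300), (-48, -18)),
    RosterEntry("E03", "excipient", "plastic", "1", "1", "II", (700, 1000), (-4, 4)),
    RosterEntry("E04", "excipient", "plastic", "1", "2A", "Ia", (900, 1100), (-45, -25)),
    RosterEntry("E05", "excipient", "plastic", "1", "1", "II", (700, 1000), (-4, 4)),
    RosterEntry("E06", "excipient", "brittle", "1", "2A", "Ib", (520, 640), (-13, -7)),
    RosterEntry("E07", "excipient", "plastic", "1", "2C", "Ia", (580, 650), (-42, -37)),
    RosterEntry("E08", "excipient", "plastic", "2A", "2A", "Ia", (750, 950), (-22, -16)),
    RosterEntry("E09", "excipient", "brittle", "2A", "2B", "Ib", (260, 330), (-10, -6)),
    RosterEntry("E10", "excipient", "elastic", "2B", "2C", "Ib", (140, 175), (-10, -6)),
    RosterEntry("E11", "excipient", "brittle", "2A", "2B", "Ib", (260, 330), (-10, -6)),
    RosterEntry("E12", "excipient", "brittle", "2A", "2A", "Ib", (400, 550), (-12, -6)),
    RosterEntry("E13", "excipient", "brittle", "2B", "2B", "II", (150, 185), (-3, 3)),
    RosterEntry("E14", "excipient", "brittle", "2A", "2A", "III", (400, 550), (7, 12)),
    RosterEntry("E15", "excipient", "brittle", "2B", "2B", "II", (170, 185), (-4.5, -1.5)),
    RosterEntry("E16", "excipient", "brittle", "2C", "2C", "II", (60, 90), (-2, 1)),
    RosterEntry("E17", "excipient", "elastic", "2B", "2B", "II", (150, 185), (-3, 3)),
    RosterEntry("N01", "natural_product", "plastic", "2A", "2B", "Ib", (260, 330), (-10, -6)),
    RosterEntry("N02", "natural_product", "plastic", "2A", "2B", "Ib", (260, 330), (-10, -6)),
    RosterEntry("N03", "natural_product", "plastic", "2A", "2B", "II", (220, 260), (-4.5, -2.5)),
    RosterEntry("N04", "natural_product", "plastic", "2A", "2A", "III", (350, 500), (6, 13)),
    RosterEntry("N05", "natural_product", "plastic", "2A", "2A", "III", (350, 500), (6, 13)),
    RosterEntry("N06", "natural_product", "plastic", "2A", "2A", "II", (300, 600), (-4, 4)),
    RosterEntry("N07", "natural_product", "plastic", "2A", "2A", "II", (300, 600), (-4, 4)),
    RosterEntry("N08", "natural_product", "plastic", "2A", "2A", "II", (300, 600), (-4, 4)),
    RosterEntry("N09", "natural_product", "plastic", "2A", "2A", "II", (300, 600), (-4, 4)),
    RosterEntry("N10", "natural_product", "plastic", "2A", "2A", "II", (300, 600), (-4, 4)),
    RosterEntry("N11", "natural_product", "plastic", "2B", "2B", "II", (150, 185), (-3, 3)),
    RosterEntry("N12", "natural_product", "plastic", "2B", "2B", "II", (150, 185), (-3, 3)),
)

# archetype → (eps at 140 MPa range, eps(10)−eps(140) range); K and P0
# follow from them, K = ln(14)/Δε, so plastic materials densify strongly
# (low K) and brittle dense materials resist compression (high K).
_POROSITY_RANGES = {
    "plastic": ((0.05, 0.15), (0.25, 0.42)),
    "brittle": ((0.10, 0.22), (0.11, 0.18)),
    "elastic": ((0.15, 0.30), (0.15, 0.25)),
}
_TRUE_DENSITY_RANGES = {
    "plastic": (1.45, 1.65),
    "brittle": (1.90, 2.90),
    "elastic": (1.40, 1.60),
}
# Nominal archetype draws for the remaining CBCS descriptors, inside the
# physically observed library spans (a: 0.708–1.05, Py: 41.6–686, etc.).
_NOMINAL_RANGES = {
    "plastic": {"a": (0.90, 1.05), "f": (0.09, 0.18), "Py": (41.6, 150.0), "kb": (4.6, 10.0)},
    "brittle": {"a": (0.708, 0.90), "f": (0.20, 0.36), "Py": (300.0, 686.0), "kb": (12.0, 24.9)},
    "elastic": {"a": (0.80, 0.95), "f": (0.03, 0.12), "Py": (150.0, 450.0), "kb": (8.0, 18.0)},
}

_POWDER_G_RANGES = {"1": (0.45, 0.65), "2A": (0.9, 1.5), "2B": (1.0, 1.6), "2C": (0.35, 0.8)}


@dataclass
class FormTruth:
    """Planted parameters for one form (powder or granule)."""

    d: float
    g: float
    K: float
    P0: float
    bulk_density: float  # Da, g·mL⁻¹
    tapped_density: float  # Dc, g·mL⁻¹
    true_density: float  # Dt, g·cm⁻³
    nominal: dict[str, float] = field(default_factory=dict)

    def porosity(self, pressure):
        return -np.log(np.asarray(pressure, dtype=float) / self.P0) / self.K

    def ts(self, pressure):
        return self.d * np.asarray(pressure, dtype=float) ** self.g

    @property
    def initial_porosity(self):
        return 1.0 - self.bulk_density / self.true_density


@dataclass
class GroundTruthMaterial:
    material_id: str
    material_class: str
    archetype: str
    powder: FormTruth
    granule: FormTruth
    planted_cotr: float = math.nan
    planted_rp: float = math.nan
    auc_p: float = math.nan
    auc_g: float = math.nan
    powder_category: str = ""
    granule_category: str = ""
    tccs_type: str = ""

    def form(self, name) -> FormTruth:
        if name == "powder":
            return self.powder
        if name == "granule":
            return self.granule
        raise KeyError(name)


@dataclass
class SyntheticLibrary:
    materials: list[GroundTruthMaterial]
    envelope: LibraryEnvelope
    seed: int
    noise_sd: float
    pressures: tuple[float, ...]
    replicates: int
    window: tuple[float, float] = DEFAULT_AUC_WINDOW
    latent_factors: np.ndarray | None = None  # (2·n_materials) × 3 scores


def _unit_auc(g, window=DEFAULT_AUC_WINDOW):
    """∫ P^g dP over the window (AUC of a power curve with d = 1)."""
    return auc_power(1.0, g, window)


def _sample_porosity_truth(rng, archetype, eps140_scale=1.0):
    (e140_lo, e140_hi), (d_lo, d_hi) = _POROSITY_RANGES[archetype]
    eps140 = rng.uniform(e140_lo, e140_hi) * eps140_scale
    delta = rng.uniform(d_lo, d_hi)
    big_k = _LN14 / delta
    p0 = 140.0 * math.exp(big_k * eps140)
    return big_k, p0, eps140 + delta  # K, P0, eps(10 MPa)


def _sample_densities(rng, archetype, eps10, z_densification=0.0, z_size=0.0):
    """Da/Dc/Dt consistent with the porosity truth (ε0 > ε at 10 MPa).

    ``z_densification`` couples the loose-bed porosity to the latent
    densification factor of the property block; ``z_size`` couples the
    Hausner ratio to the particle-size factor (fine cohesive powders tap
    down further, so IH — and with it IC and Ie — anticorrelates with
    particle size).
    """
    dt_lo, dt_hi = _TRUE_DENSITY_RANGES[archetype]
    dt = rng.uniform(dt_lo, dt_hi)
    eps0_mid = min(max(0.68 + 0.05 * z_densification, eps10 + 0.07), 0.80)
    eps0 = float(np.clip(rng.normal(eps0_mid, 0.02), eps10 + 0.05, 0.82))
    da = dt * (1.0 - eps0)
    ih = float(
        np.clip(rng.normal(1.28 - 0.04 * z_size + 0.04 * z_densification, 0.12), 1.03, 1.6)
    )
    dc = min(da * ih, dt * 0.98)
    return da, dc, dt


def _sample_nominal(rng, archetype):
    out = {}
    for key, (lo, hi) in _NOMINAL_RANGES[archetype].items():
        out[key] = rng.uniform(lo, hi)
    out["b"] = rng.uniform(0.01, 0.2)
    out["TS0"] = rng.uniform(2.0, 15.0)
    return out


def _boundary_margin(d, g, acceptable_ts=2.0, good_ts=3.0):
    """Smallest relative distance of (d, g) from any CBCS decision boundary;
    used to pick noise-robust planted parameters."""
    ts50, ts100, ts140 = d * 50.0**g, d * 100.0**g, d * 140.0**g
    return min(
        abs(ts50 - good_ts) / good_ts,
        abs(ts100 - acceptable_ts) / acceptable_ts,
        abs(ts140 - good_ts) / good_ts,
        abs(ts140 - acceptable_ts) / acceptable_ts,
        abs(d - 0.2) / 0.2,
        abs(g - 0.95) / 0.95,
    )


def _solve_powder_tabletability(rng, entry: RosterEntry, window):
    """Draw (d, g) for a powder matching its planted category and AUC range."""
    target = CBCSCategory(entry.powder_category)
    g_lo, g_hi = _POWDER_G_RANGES[entry.powder_category]
    best = None
    for _ in range(200):
        auc = rng.uniform(*entry.auc_p_range)
        g = rng.uniform(g_lo, g_hi)
        d = auc / _unit_auc(g, window)
        if d > 1.05:
            continue
        if classify_cbcs(d, g).category is target:
            margin = _boundary_margin(d, g)
            if best is None or margin > best[3]:
                best = (d, g, auc, margin)
            if margin > 0.15:
                break
    if best is None:
        raise RuntimeError(
            f"{entry.material_id}: could not realise powder category {target.value} "
            f"with AUC in {entry.auc_p_range}"
        )
    return best[0], best[1], best[2]


def _solve_granule_shape(entry: RosterEntry, auc_g, window, g_grid=None):
    """Given the granule AUC fixed by the CoTr plant, pick the pressure
    sensitivity g (hence d = AUCg/∫P^g) that lands in the planted granule
    category with the largest classification margin."""
    target = CBCSCategory(entry.granule_category)
    if g_grid is None:
        g_grid = np.linspace(0.40, 1.75, 136)
    best = None
    for g in g_grid:
        d = auc_g / _unit_auc(g, window)
        if not 0 < d <= 1.1:
            continue
        if classify_cbcs(d, g).category is target:
            margin = _boundary_margin(d, g)
            if best is None or margin > best[2]:
                best = (d, float(g), margin)
    if best is None:
        raise RuntimeError(
            f"{entry.material_id}: granule category {target.value} infeasible "
            f"for AUCg = {auc_g:.1f} MPa²"
        )
    return best[0], best[1]


def make_material(seed, archetype, material_id="M1", material_class="excipient"):
    """Sample one ground-truth material of the given deformation archetype.

    Plastic materials get low yield pressures and strong tabletability,
    brittle ones high fragmentation/yield-pressure draws, elastic ones weak
    bonding and low d.  The same seed always returns the identical
    material.  The granule form initially mirrors the powder (no planted
    tabletability change); use :func:`make_pair_with_cotr` or
    :func:`make_library` to plant one.
    """
    if archetype not in _POROSITY_RANGES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(seed)
    d_ranges = {"plastic": (0.2, 1.0), "brittle": (0.002, 0.05), "elastic": (1e-4, 0.01)}
    g_ranges = {"plastic": (0.4, 0.9), "brittle": (0.9, 1.5), "elastic": (1.0, 1.7)}
    forms = {}
    for form_name in ("powder", "granule"):
        big_k, p0, eps10 = _sample_porosity_truth(rng, archetype)
        da, dc, dt = _sample_densities(rng, archetype, eps10)
        d = rng.uniform(*d_ranges[archetype])
        g = rng.uniform(*g_ranges[archetype])
        forms[form_name] = FormTruth(
            d=d, g=g, K=big_k, P0=p0,
            bulk_density=da, tapped_density=dc, true_density=dt,
            nominal=_sample_nominal(rng, archetype),
        )
    return GroundTruthMaterial(
        material_id=material_id,
        material_class=material_class,
        archetype=archetype,
        powder=forms["powder"],
        granule=forms["granule"],
    )


def make_pair_with_cotr(material: GroundTruthMaterial, target_cotr, envelope, window=DEFAULT_AUC_WINDOW):
    """Rescale the granule d so that AUCg − AUCp = (target/100)·Amax.

    The area is linear in d, so the required granule d has the closed form
    d_g = (AUCp + (target/100)·Amax) / ∫P^{g_g} dP.  A non-positive
    required d is infeasible and raises.
    """
    if abs(target_cotr) > 100:
        raise ValueError(f"|target CoTr| must be <= 100, got {target_cotr}")
    auc_p = auc_power(material.powder.d, material.powder.g, window)
    auc_g = auc_p + (target_cotr / 100.0) * envelope.a_max
    if auc_g <= 0:
        raise ValueError(
            f"{material.material_id}: target CoTr {target_cotr}% requires a "
            f"non-positive granule area ({auc_g:.1f} MPa²)"
        )
    d_g = auc_g / _unit_auc(material.granule.g, window)
    material.granule.d = d_g
    material.auc_p = auc_p
    material.auc_g = auc_g
    material.planted_cotr = target_cotr
    material.planted_rp = 100.0 * auc_g / auc_p
    return d_g


def generate_curves(material: GroundTruthMaterial, pressures=DEFAULT_PRESSURES,
                    noise_sd=0.01, replicates=2, seed=None, rng=None):
    """Noisy replicate porosity/TS observations for both forms.

    Porosity follows the planted Gurnham curve and TS the planted power
    curve, each with multiplicative log-normal noise of relative magnitude
    ``noise_sd``.  Returns ``{form: (P, ε, TS)}`` with ``replicates`` rows
    per pressure; parameters putting ε outside (0, 1) on the grid raise.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pressures = np.asarray(pressures, dtype=float)
    if np.any(pressures <= 0) or np.any(pressures > 200):
        raise ValueError("pressures must lie in (0, 200] MPa")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    out = {}
    for form_name in ("powder", "granule"):
        truth = material.form(form_name)
        eps_true = truth.porosity(pressures)
        if np.any(eps_true <= 0) or np.any(eps_true >= 1):
            raise ValueError(
                f"{material.material_id}/{form_name}: planted parameters give "
                f"porosity outside (0, 1) on the pressure grid"
            )
        ts_true = truth.ts(pressures)
        p_rep = np.repeat(pressures, replicates)
        eps = np.repeat(eps_true, replicates) * np.exp(
            rng.normal(0.0, noise_sd, p_rep.size) if noise_sd else 0.0
        )
        ts = np.repeat(ts_true, replicates) * np.exp(
            rng.normal(0.0, noise_sd, p_rep.size) if noise_sd else 0.0
        )
        out[form_name] = (p_rep, np.clip(eps, 1e-6, 1 - 1e-6), ts)
    return out


# ---------------------------------------------------------------------------
# property block

_PROPERTY_LOADINGS = {
    # column: (size/flow factor, densification factor, hygroscopicity factor)
    "D50_um": (0.88, 0.0, -0.15),
    "D10_um": (0.30, 0.0, 0.0),  # expressed as a fraction of D50
    "D90_um": (0.30, 0.30, 0.0),  # expressed as a multiple of D50
    "pct_Pf": (-0.85, 0.0, 0.10),
    "I_theta": (0.70, 0.0, 0.0),
    "IH": (-0.60, 0.25, 0.10),
    "SFp": (0.0, 0.80, -0.20),
    "t_flow_min": (-0.80, 0.0, 0.30),
    "AOR_deg": (-0.75, 0.0, 0.30),
    "pct_H": (-0.20, 0.0, 0.90),
    "pct_HR": (0.0, 0.0, 0.85),
    "Icd_N": (-0.78, 0.20, 0.25),
}
# latent-factor mean shifts: natural products are finer/more hygroscopic,
# granules coarser and better flowing than the parent powder
_CLASS_SHIFTS = {"excipient": (0.45, 0.0, -0.75), "natural_product": (-0.65, 0.0, 1.05)}
_FORM_SHIFTS = {"powder": (0.0, 0.0, 0.0), "granule": (0.70, -0.15, 0.0)}


def _latent_scores(rng, materials, forms=("powder", "granule")):
    rows = []
    scores = []
    for mat in materials:
        base = rng.normal(0.0, 1.0, 3)
        for form_name in forms:
            wobble = rng.normal(0.0, 0.35, 3)  # granule correlated with its powder
            z = (
                base
                + wobble
                + np.array(_CLASS_SHIFTS[mat.material_class])
                + np.array(_FORM_SHIFTS[form_name])
            )
            rows.append((mat.material_id, form_name))
            scores.append(z)
    return rows, np.asarray(scores)


def make_property_block(materials, seed=None, rng=None, factors=None) -> pd.DataFrame:
    """Correlated 19-descriptor table, one row per material × form.

    Standardised latent values z_j = L_j·F + unique noise are mapped onto
    physical scales per column; the densities Da/Dc/Dt come from the
    compression ground truth (Dc via a factor-driven Hausner ratio), and
    span, IC, Ie and εp are exact transforms of their parents so the
    printed invariants (Da <= Dc <= Dt, SFp + εp = 1) hold by construction.

    ``factors`` lets a library pass the latent scores its density truths
    were sampled against (see :func:`make_library`); when omitted, fresh
    scores are drawn from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if factors is None:
        labels, factors = _latent_scores(rng, materials)
    else:
        labels = [
            (mat.material_id, form) for mat in materials for form in ("powder", "granule")
        ]
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (len(labels), 3):
            raise ValueError(f"factors must have shape {(len(labels), 3)}")
    z = {}
    for col, load in _PROPERTY_LOADINGS.items():
        load = np.asarray(load)
        unique = math.sqrt(max(1.0 - float(load @ load), 0.02))
        z[col] = factors @ load + rng.normal(0.0, unique, len(labels))

    d50 = np.exp(3.1 + 0.55 * z["D50_um"])
    d10 = d50 * (0.15 + 0.12 * norm.cdf(z["D10_um"]))
    d90 = d50 * (2.2 + 1.8 * norm.cdf(z["D90_um"]))
    frame = pd.DataFrame(index=range(len(labels)))
    frame["material_id"] = [m for m, _ in labels]
    frame["form"] = [f for _, f in labels]
    frame["material_class"] = [
        next(m.material_class for m in materials if m.material_id == mid)
        for mid, _ in labels
    ]
    frame["D10_um"] = d10
    frame["D50_um"] = d50
    frame["D90_um"] = d90
    frame["span"] = (d90 - d10) / d50
    frame["pct_Pf"] = np.clip(45.0 + 25.0 * z["pct_Pf"], 0.5, 99.5)
    frame["I_theta"] = np.clip(0.006 + 0.004 * z["I_theta"], 1e-4, 0.025)
    da, dc, dt = [], [], []
    for mat in materials:
        for form_name in ("powder", "granule"):
            truth = mat.form(form_name)
            da.append(truth.bulk_density)
            dc.append(truth.tapped_density)
            dt.append(truth.true_density)
    frame["Da_g_mL"] = da
    frame["Dc_g_mL"] = dc
    frame["Dt_g_cm3"] = dt
    frame["IH"] = frame["Dc_g_mL"] / frame["Da_g_mL"]
    frame["IC"] = 100.0 * (1.0 - frame["Da_g_mL"] / frame["Dc_g_mL"])
    frame["Ie"] = (frame["Dc_g_mL"] - frame["Da_g_mL"]) / (
        frame["Dc_g_mL"] * frame["Da_g_mL"]
    )
    frame["SFp"] = np.clip(0.42 + 0.12 * z["SFp"], 0.08, 0.85)
    frame["eps_p"] = 1.0 - frame["SFp"]
    frame["t_flow_min"] = np.exp(0.4 + 0.55 * z["t_flow_min"])
    frame["AOR_deg"] = np.clip(43.0 + 5.5 * z["AOR_deg"], 25.0, 60.0)
    frame["pct_H"] = np.clip(np.exp(1.6 + 1.0 * z["pct_H"]), 0.003, 24.0)
    frame["pct_HR"] = np.clip(4.5 + 2.8 * z["pct_HR"], 0.05, 15.0)
    frame["Icd_N"] = np.clip(150.0 + 85.0 * z["Icd_N"], 5.0, 400.0)
    return frame[["material_id", "form", "material_class"] + PROPERTY_COLUMNS]


# ---------------------------------------------------------------------------
# library assembly


def make_library(
    n_materials=29,
    seed=0,
    noise_sd=0.01,
    pressures=DEFAULT_PRESSURES,
    replicates=2,
    window=DEFAULT_AUC_WINDOW,
) -> SyntheticLibrary:
    """Build the planted synthetic library.

    The default ``n_materials=29`` uses the full roster; smaller values
    take a roster prefix (planted type shares then deviate from the
    defaults).  Construction order: draw powder tabletability inside each
    entry's AUC band, plant CoTr targets, solve the coupled
    granule-area/envelope fixed point (the envelope depends on the granule
    areas it helps to plant — the map is a contraction for |CoTr| < 100%),
    then pick each granule's pressure sensitivity to land in its planted
    category, and finally attach porosity truths, densities and the
    property block.
    """
    if not 2 <= n_materials <= len(ROSTER):
        raise ValueError(f"n_materials must be in [2, {len(ROSTER)}]")
    master = np.random.default_rng(seed)
    seeds = master.spawn(4)
    rng_powder, rng_porosity, rng_props, _ = seeds

    entries = ROSTER[:n_materials]
    materials: list[GroundTruthMaterial] = []
    auc_p = np.empty(n_materials)
    cotr = np.empty(n_materials)
    g_powder = np.empty(n_materials)
    for i, entry in enumerate(entries):
        d_p, g_p, auc = _solve_powder_tabletability(rng_powder, entry, window)
        auc_p[i] = auc
        g_powder[i] = g_p
        cotr[i] = rng_powder.uniform(*entry.cotr_range)
        mat = GroundTruthMaterial(
            material_id=entry.material_id,
            material_class=entry.material_class,
            archetype=entry.archetype,
            powder=FormTruth(d=d_p, g=g_p, K=1.0, P0=1.0, bulk_density=0.5,
                             tapped_density=0.6, true_density=1.5),
            granule=FormTruth(d=d_p, g=g_p, K=1.0, P0=1.0, bulk_density=0.5,
                              tapped_density=0.6, true_density=1.5),
        )
        materials.append(mat)

    # fixed point: granule areas and the envelope determine each other
    auc_g = auc_p.copy()
    for _ in range(500):
        env = library_envelope(np.concatenate([auc_p, auc_g]))
        auc_g_new = auc_p + (cotr / 100.0) * env.a_max
        if np.any(auc_g_new <= 0):
            bad = entries[int(np.argmin(auc_g_new))].material_id
            raise RuntimeError(f"planted CoTr infeasible for {bad} (AUCg <= 0)")
        if np.max(np.abs(auc_g_new - auc_g)) < 1e-10:
            auc_g = auc_g_new
            break
        auc_g = auc_g_new
    env = library_envelope(np.concatenate([auc_p, auc_g]))

    for i, (entry, mat) in enumerate(zip(entries, materials)):
        d_g, g_g = _solve_granule_shape(entry, auc_g[i], window)
        mat.granule.d, mat.granule.g = d_g, g_g
        mat.auc_p, mat.auc_g = float(auc_p[i]), float(auc_g[i])
        mat.planted_cotr = float(cotr[i])
        mat.planted_rp = float(100.0 * auc_g[i] / auc_p[i])
        mat.powder_category = classify_cbcs(mat.powder.d, mat.powder.g).category.value
        mat.granule_category = classify_cbcs(d_g, g_g).category.value
        assert mat.powder_category == entry.powder_category
        assert mat.granule_category == entry.granule_category
        mat.tccs_type = entry.tccs_type

    # latent property factors, shared with the property block so the
    # density-derived columns (IH, IC, Ie) carry the size anticorrelation
    _, factors = _latent_scores(np.random.default_rng([seed, 4]), materials)

    for i, mat in enumerate(materials):
        # porosity / density truths per form
        for j, form_name in enumerate(("powder", "granule")):
            truth = mat.form(form_name)
            big_k, p0, eps10 = _sample_porosity_truth(rng_porosity, mat.archetype)
            z_size, z_dens = factors[2 * i + j, 0], factors[2 * i + j, 1]
            da, dc, dt = _sample_densities(
                rng_porosity, mat.archetype, eps10, z_dens, z_size
            )
            truth.K, truth.P0 = big_k, p0
            truth.bulk_density, truth.tapped_density, truth.true_density = da, dc, dt
            truth.nominal = _sample_nominal(rng_porosity, mat.archetype)

    lib = SyntheticLibrary(
        latent_factors=factors,
        materials=materials,
        envelope=env,
        seed=seed,
        noise_sd=noise_sd,
        pressures=tuple(float(p) for p in pressures),
        replicates=replicates,
        window=window,
    )
    return lib


def library_tables(lib: SyntheticLibrary, punch_diameter_mm=10.0, fill_mass_g=0.300):
    """Materialise the library as the pipeline's input tables.

    Returns ``(materials, tablets, ground_truth)`` DataFrames.  Raw tablet
    rows are back-computed from the noisy porosity/TS draws: thickness from
    the apparent density at the fill mass, crush force from TS, applied
    force from the nominal pressure — so the tablet-mechanics stage
    recovers exactly the simulated states.
    """
    rng = np.random.default_rng([lib.seed, 3])  # curve-noise stream
    materials_df = make_property_block(
        lib.materials,
        rng=np.random.default_rng([lib.seed, 2]),
        factors=lib.latent_factors,
    )
    area_mm2 = math.pi * (punch_diameter_mm / 2.0) ** 2
    rows = []
    for mat in lib.materials:
        curves = generate_curves(
            mat, lib.pressures, lib.noise_sd, lib.replicates, rng=rng
        )
        for form_name, (p, eps, ts) in curves.items():
            dt = mat.form(form_name).true_density
            rho_app = dt * (1.0 - eps)
            thickness = 1000.0 * fill_mass_g / (rho_app * area_mm2)
            crush = ts * math.pi * punch_diameter_mm * thickness / 2.0
            force = punch_force(p, punch_diameter_mm)
            for j in range(len(p)):
                rows.append(
                    {
                        "material_id": mat.material_id,
                        "form": form_name,
                        "applied_force_kN": force[j],
                        "mass_g": fill_mass_g,
                        "diameter_mm": punch_diameter_mm,
                        "thickness_mm": thickness[j],
                        "crush_force_N": crush[j],
                    }
                )
    tablets_df = pd.DataFrame(rows)
    truth_rows = []
    for mat in lib.materials:
        for form_name in ("powder", "granule"):
            truth = mat.form(form_name)
            truth_rows.append(
                {
                    "material_id": mat.material_id,
                    "form": form_name,
                    "material_class": mat.material_class,
                    "archetype": mat.archetype,
                    "d": truth.d,
                    "g": truth.g,
                    "K": truth.K,
                    "P0": truth.P0,
                    "Da_g_mL": truth.bulk_density,
                    "Dc_g_mL": truth.tapped_density,
                    "Dt_g_cm3": truth.true_density,
                    "auc": mat.auc_p if form_name == "powder" else mat.auc_g,
                    "planted_cotr": mat.planted_cotr,
                    "planted_rp": mat.planted_rp,
                    "planted_category": (
                        mat.powder_category if form_name == "powder" else mat.granule_category
                    ),
                    "planted_tccs_type": mat.tccs_type,
                }
            )
    return materials_df, tablets_df, pd.DataFrame(truth_rows)


def planted_summary(lib: SyntheticLibrary) -> dict:
    """Planted library book-keeping: type shares and downgrade share (%)."""
    n = len(lib.materials)
    types = [m.tccs_type for m in lib.materials]
    downgrades = sum(
        CBCSCategory(m.granule_category).rank < CBCSCategory(m.powder_category).rank
        for m in lib.materials
    )
    return {
        "n_materials": n,
        "share_type_I_percent": 100.0 * sum(t in ("Ia", "Ib") for t in types) / n,
        "share_type_II_percent": 100.0 * types.count("II") / n,
        "share_type_III_percent": 100.0 * types.count("III") / n,
        "share_downgrade_percent": 100.0 * downgrades / n,
    }
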