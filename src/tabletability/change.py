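"""Change-of-tabletability indices: AUC, library envelope, RP and CoTr.

The tabletability of a form is summarised by the area under its
TS–pressure profile over the tableting window (10–140 MPa by default).
The legacy reworking potential is RP = 100·AUCg/AUCp.  The relative
change of tabletability normalises the signed area change by the
library-wide envelope width:

    CoTr = 100 · (AUCg − AUCp) / (AUCmax − AUCmin)

with AUCmax/AUCmin taken over every powder and granule profile in the
library.  Loss of tabletability therefore carries a negative sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DEFAULT_AUC_WINDOW = (10.0, 140.0)

__all__ = [
    "LibraryEnvelope",
    "ChangeIndices",
    "UndefinedIndexError",
    "auc_power",
    "auc_trapezoid",
    "library_envelope",
    "reworking_potential",
    "relative_change_of_tabletability",
    "change_indices",
]


class UndefinedIndexError(ValueError):
    """A change index is undefined for the given inputs (e.g. Amax = 0)."""


@dataclass(frozen=True)
class LibraryEnvelope:
    """Extreme tabletability areas across the whole library, MPa²."""

    auc_max: float
    auc_min: float

    def __post_init__(self):
        if self.auc_min < 0 or self.auc_max < self.auc_min:
            raise ValueError(f"invalid envelope ({self.auc_max}, {self.auc_min})")

    @property
    def a_max(self) -> float:
        return self.auc_max - self.auc_min


@dataclass(frozen=True)
class ChangeIndices:
    material_id: str
    auc_p: float
    auc_g: float
    rp_percent: float
    ct: float  # AUCg − AUCp, MPa²
    cotr_percent: float


def auc_power(d, g, window=DEFAULT_AUC_WINDOW):
    """Closed-form area under TS = d·P^g over the pressure window, MPa².

    ∫ d·P^g dP = d·(Pmax^{g+1} − Pmin^{g+1})/(g+1); the g = −1 case falls
    back to the logarithmic antiderivative d·ln(Pmax/Pmin).
    """
    lo, hi = window
    if not (d > 0 and hi > lo > 0):
        raise ValueError(f"need d > 0 and a positive window, got d={d}, window={window}")
    if not g > -1 and not math.isclose(g, -1.0):
        raise ValueError(f"exponent g={g} gives a divergent area on {window}")
    if math.isclose(g, -1.0):
        return d * math.log(hi / lo)
    return d * (hi ** (g + 1) - lo ** (g + 1)) / (g + 1)


def auc_trapezoid(pressure, ts, window=DEFAULT_AUC_WINDOW):
    """Composite-trapezoid area under measured (P, TS) points, MPa².

    Points are sorted by pressure and clipped to the window, interpolating
    the TS value at a window edge when points straddle it.  Requires at
    least two points inside the window.
    """
    lo, hi = window
    pressure = np.asarray(pressure, dtype=float)
    ts = np.asarray(ts, dtype=float)
    order = np.argsort(pressure)
    pressure, ts = pressure[order], ts[order]
    inside = (pressure >= lo) & (pressure <= hi)
    if int(np.sum(inside)) < 2:
        raise ValueError(f"need >= 2 points inside window {window}, got {int(np.sum(inside))}")
    p_in, ts_in = pressure[inside], ts[inside]
    # interpolate onto the window edges when measurements extend beyond them
    if pressure[0] < lo < p_in[0]:
        p_in = np.concatenate([[lo], p_in])
        ts_in = np.concatenate([[np.interp(lo, pressure, ts)], ts_in])
    if pressure[-1] > hi > p_in[-1]:
        p_in = np.concatenate([p_in, [hi]])
        ts_in = np.concatenate([ts_in, [np.interp(hi, pressure, ts)]])
    return float(np.trapezoid(ts_in, p_in))


def library_envelope(aucs) -> LibraryEnvelope:
    """Envelope (AUCmax, AUCmin) over every powder and granule AUC."""
    aucs = np.asarray(list(aucs), dtype=float)
    if len(aucs) < 2:
        raise ValueError("the envelope needs at least two tabletability curves")
    if np.any(~np.isfinite(aucs)) or np.any(aucs < 0):
        raise ValueError("AUC values must be finite and non-negative")
    return LibraryEnvelope(auc_max=float(np.max(aucs)), auc_min=float(np.min(aucs)))


def reworking_potential(auc_g, auc_p):
    """RP = 100·AUCg/AUCp, percent."""
    if not auc_p > 0:
        raise UndefinedIndexError(f"reworking potential undefined for AUCp = {auc_p}")
    return 100.0 * auc_g / auc_p


def relative_change_of_tabletability(auc_g, auc_p, envelope: LibraryEnvelope):
    """CoTr = 100·(AUCg − AUCp)/Amax, percent; negative means loss."""
    if not envelope.a_max > 0:
        raise UndefinedIndexError(
            "CoTr undefined: all library AUCs are equal (Amax = 0)"
        )
    return 100.0 * (auc_g - auc_p) / envelope.a_max


def change_indices(material_id, auc_p, auc_g, envelope: LibraryEnvelope) -> ChangeIndices:
    """Assemble RP, Ct and CoTr for one powder/granule pair."""
    return ChangeIndices(
        material_id=material_id,
        auc_p=auc_p,
        auc_g=auc_g,
        rp_percent=reworking_potential(auc_g, auc_p),
        ct=auc_g - auc_p,
        cotr_percent=relative_change_of_tabletability(auc_g, auc_p, envelope),
    )
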