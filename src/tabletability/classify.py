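"""CBCS tabletability categories and TCCS tabletability-change types.

CBCS categories (1, 2A, 2B, 2C) grade how strong a tablet the material
makes across the 10–140 MPa tableting range; category 1 is the best
(good tabletability already at 20–50 MPa) and 2C the floor (unacceptable
everywhere).  Because the published d/g numeric gates overlap, the 2A/2B/2C
split is decided by evaluating the fitted tabletability curve TS = d·P^g at
the pressure-band upper edges against the TS >= 2 MPa (acceptable) and
TS >= 3 MPa (good) thresholds; the curve-shape rule also covers the
low-d/high-g materials (d < 0.002 with g >= 1.6) that the d gate alone
would misplace.

TCCS types grade the relative change of tabletability after granulation:
Ia (large loss, CoTr < −15%), Ib (moderate loss, −15% <= CoTr < −5%),
II (unchanged, −5% <= CoTr <= 5%), III (gain, CoTr > 5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "TCCSType",
    "CBCSCategory",
    "CategoryChange",
    "classify_tccs",
    "classify_cbcs",
    "downgrade_report",
]


class TCCSType(str, Enum):
    IA = "Ia"
    IB = "Ib"
    II = "II"
    III = "III"


class CBCSCategory(str, Enum):
    CAT_1 = "1"
    CAT_2A = "2A"
    CAT_2B = "2B"
    CAT_2C = "2C"

    @property
    def rank(self) -> int:
        """Quality ordering 1 > 2A > 2B > 2C (larger is better)."""
        return {"1": 3, "2A": 2, "2B": 1, "2C": 0}[self.value]


# TCCS thresholds in CoTr percent; II is closed on both ends.
TCCS_LARGE_LOSS = -15.0
TCCS_MODERATE_LOSS = -5.0
TCCS_GAIN = 5.0


def classify_tccs(cotr_percent: float) -> TCCSType:
    """Assign the TCCS type from CoTr (percent).

    The four intervals partition the real line: Ia on (−inf, −15),
    Ib on [−15, −5), II on [−5, 5] and III on (5, inf).
    """
    if not math.isfinite(cotr_percent):
        raise ValueError(f"CoTr must be finite, got {cotr_percent!r}")
    if cotr_percent < TCCS_LARGE_LOSS:
        return TCCSType.IA
    if cotr_percent < TCCS_MODERATE_LOSS:
        return TCCSType.IB
    if cotr_percent <= TCCS_GAIN:
        return TCCSType.II
    return TCCSType.III


@dataclass(frozen=True)
class CBCSResult:
    category: CBCSCategory
    rationale: str


def classify_cbcs(
    d: float,
    g: float,
    acceptable_ts: float = 2.0,
    good_ts: float = 3.0,
) -> CBCSResult:
    """Assign the CBCS tabletability category from the power-law fit.

    Category 1 requires d >= 0.2 with 0 < g < 0.95 AND the curve actually
    delivering good tabletability at the low band (TS(50) >= good) — the
    published d/g gate alone admits flat weak curves that the band test
    rightly demotes.  Otherwise the fitted curve is evaluated at the band
    upper edges (TS is monotone increasing in P for g > 0): 2A needs
    TS(100) >= acceptable and TS(140) >= good; 2B needs TS(140) >=
    acceptable; everything else is 2C.
    """
    if not d > 0:
        raise ValueError(f"d must be positive, got {d}")
    if not math.isfinite(g):
        raise ValueError(f"g must be finite, got {g!r}")
    if d >= 0.2 and 0 < g < 0.95 and d * 50.0**g >= good_ts:
        return CBCSResult(
            CBCSCategory.CAT_1,
            f"d={d:.3g} >= 0.2, 0 < g={g:.3g} < 0.95 and TS(50)={d * 50.0**g:.3g} "
            f">= {good_ts:g}",
        )
    ts100 = d * 100.0**g
    ts140 = d * 140.0**g
    if ts100 >= acceptable_ts and ts140 >= good_ts:
        return CBCSResult(
            CBCSCategory.CAT_2A,
            f"TS(100)={ts100:.3g} >= {acceptable_ts:g} and TS(140)={ts140:.3g} >= {good_ts:g}",
        )
    if ts140 >= acceptable_ts:
        return CBCSResult(
            CBCSCategory.CAT_2B, f"TS(140)={ts140:.3g} >= {acceptable_ts:g}"
        )
    return CBCSResult(
        CBCSCategory.CAT_2C, f"TS(140)={ts140:.3g} < {acceptable_ts:g} everywhere"
    )


@dataclass(frozen=True)
class CategoryChange:
    powder: CBCSCategory
    granule: CBCSCategory

    @property
    def is_downgrade(self) -> bool:
        return self.granule.rank < self.powder.rank

    @property
    def is_upgrade(self) -> bool:
        return self.granule.rank > self.powder.rank


def downgrade_report(powder: CBCSCategory, granule: CBCSCategory) -> CategoryChange:
    """Ordered (from, to) category change with downgrade flag."""
    return CategoryChange(powder=CBCSCategory(powder), granule=CBCSCategory(granule))
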