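"""The six compression models behind the CBCS parameter set.

Compressibility (porosity–pressure): Kawakita, Shapiro, Heckel, Gurnham.
Compactability (porosity–TS): Ryshkewitch–Duckworth.
Tabletability (TS–pressure): power law TS = d·P^g.

All fits are ordinary least squares on the model's linearised form over the
model's stated pressure window (Shapiro 0–50 MPa, everything else
10–140 MPa).  A failed fit is a value, not an exception, so a whole-library
run always completes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

KAWAKITA_WINDOW = (10.0, 140.0)
SHAPIRO_WINDOW = (0.0, 50.0)
HECKEL_WINDOW = (10.0, 140.0)
GURNHAM_WINDOW = (10.0, 140.0)
RD_WINDOW = (10.0, 140.0)
POWER_WINDOW = (10.0, 140.0)

__all__ = [
    "CompressionCurve",
    "FitResult",
    "CBCSParameters",
    "engineering_strain",
    "fit_kawakita",
    "fit_shapiro",
    "fit_heckel",
    "fit_gurnham",
    "fit_ryshkewitch_duckworth",
    "fit_power",
    "fit_all",
]


@dataclass
class CompressionCurve:
    """Replicate-averaged out-of-die compression data for one material form.

    ``pressure`` (MPa), ``porosity`` and ``tensile_strength`` (MPa) are
    parallel arrays sorted by ascending pressure.  ``bulk_density`` (Da,
    g·mL⁻¹) and ``true_density`` (Dt, g·cm⁻³) belong to the same form and
    feed the Kawakita engineering strain and the Shapiro initial porosity
    ε0 = 1 − Da/Dt.
    """

    material_id: str
    form: str
    pressure: np.ndarray
    porosity: np.ndarray
    tensile_strength: np.ndarray
    bulk_density: float
    true_density: float

    def __post_init__(self):
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.porosity = np.asarray(self.porosity, dtype=float)
        self.tensile_strength = np.asarray(self.tensile_strength, dtype=float)
        if not (self.pressure.shape == self.porosity.shape == self.tensile_strength.shape):
            raise ValueError("pressure, porosity and tensile_strength must align")
        if np.any(self.pressure <= 0):
            raise ValueError(f"{self.material_id}/{self.form}: pressures must be positive")
        order = np.argsort(self.pressure)
        self.pressure = self.pressure[order]
        self.porosity = self.porosity[order]
        self.tensile_strength = self.tensile_strength[order]
        if len(self.pressure) < 4 or len(np.unique(self.pressure)) < 3:
            raise ValueError(
                f"{self.material_id}/{self.form}: need >= 4 points spanning "
                f">= 3 distinct pressures, got {len(self.pressure)}"
            )
        if np.any((self.porosity <= 0) | (self.porosity >= 1)):
            raise ValueError(
                f"{self.material_id}/{self.form}: porosity must lie in (0, 1)"
            )

    @property
    def initial_porosity(self) -> float:
        """ε0 of the loose bed, from the measured bulk and true density."""
        return 1.0 - self.bulk_density / self.true_density

    def apparent_density(self) -> np.ndarray:
        return self.true_density * (1.0 - self.porosity)


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    r2: float
    rmse: float
    n_points: int
    window: tuple[float, float]
    ok: bool = True
    message: str = ""

    @classmethod
    def failure(cls, model, message, window, n_points=0, params=None):
        return cls(
            model=model,
            params=params or {},
            r2=math.nan,
            rmse=math.nan,
            n_points=n_points,
            window=window,
            ok=False,
            message=message,
        )


@dataclass
class CBCSParameters:
    """The nine CBCS descriptors (a, ab, b⁻¹, f, Py, K, kb, d, g) plus the
    auxiliary constants of each model and per-model diagnostics."""

    material_id: str
    form: str
    a: float = math.nan
    b: float = math.nan  # MPa⁻¹
    b_inv: float = math.nan  # MPa
    ab: float = math.nan
    f: float = math.nan  # MPa^−0.5
    k_shapiro: float = math.nan  # MPa⁻¹
    Py: float = math.nan  # MPa
    heckel_A: float = math.nan
    K: float = math.nan
    P0: float = math.nan  # MPa
    kb: float = math.nan
    TS0: float = math.nan  # MPa
    d: float = math.nan
    g: float = math.nan
    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def n_ok(self) -> int:
        return sum(fit.ok for fit in self.fits.values())


def _in_window(pressure, window):
    lo, hi = window
    if not hi > lo:
        raise ValueError(f"degenerate pressure window {window}")
    return (pressure >= lo) & (pressure <= hi)


def _linear_diag(x, y, yhat):
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-20 else 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / len(y))
    return r2, rmse


def engineering_strain(curve: CompressionCurve):
    """Kawakita degree of volume reduction C = 1 − Da/ρapp per point.

    The initial bed volume is set from the bulk density; points where the
    tablet is no denser than the loose bed (C <= 0) are excluded with a
    warning.  Returns (pressure, C) arrays.
    """
    rho_app = curve.apparent_density()
    c = 1.0 - curve.bulk_density / rho_app
    keep = c > 0
    if not np.all(keep):
        warnings.warn(
            f"{curve.material_id}/{curve.form}: dropped {int(np.sum(~keep))} "
            "point(s) with non-positive engineering strain",
            stacklevel=2,
        )
    return curve.pressure[keep], c[keep]


def fit_kawakita(curve: CompressionCurve, window=KAWAKITA_WINDOW) -> FitResult:
    """Kawakita fit via the linearised form P/C = P/a + 1/(ab).

    OLS of P/C on P; a = 1/slope, b = slope/intercept.
    """
    p, c = engineering_strain(curve)
    keep = _in_window(p, window)
    p, c = p[keep], c[keep]
    if len(p) < 3:
        return FitResult.failure("kawakita", f"only {len(p)} usable points in window", window)
    y = p / c
    res = stats.linregress(p, y)
    if res.slope <= 0 or res.intercept <= 0:
        return FitResult.failure(
            "kawakita",
            f"non-physical linearised fit (slope={res.slope:.3g}, "
            f"intercept={res.intercept:.3g})",
            window,
            n_points=len(p),
            params={"slope": res.slope, "intercept": res.intercept},
        )
    a = 1.0 / res.slope
    b = res.slope / res.intercept
    r2, rmse = _linear_diag(p, y, res.slope * p + res.intercept)
    return FitResult(
        "kawakita",
        {"a": a, "b": b, "ab": a * b, "b_inv": 1.0 / b},
        r2,
        rmse,
        len(p),
        window,
    )


def fit_shapiro(curve: CompressionCurve, window=SHAPIRO_WINDOW, eps0=None) -> FitResult:
    """Shapiro fit ln ε = ln ε0 − kP − f√P over the low-pressure window.

    The intercept is fixed at ln ε0 with ε0 from the bulk/true density
    ratio; k and f come from a no-intercept least squares on (−P, −√P).
    """
    if eps0 is None:
        eps0 = curve.initial_porosity
    if not 0 < eps0 < 1:
        return FitResult.failure("shapiro", f"initial porosity {eps0:.3g} outside (0,1)", window)
    keep = _in_window(curve.pressure, window) & (curve.pressure > 0)
    p = curve.pressure[keep]
    eps = curve.porosity[keep]
    if len(p) < 3:
        return FitResult.failure("shapiro", f"only {len(p)} points in window", window)
    y = np.log(eps) - math.log(eps0)
    design = np.column_stack([-p, -np.sqrt(p)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    k, f = coef
    r2, rmse = _linear_diag(p, y, design @ coef)
    return FitResult("shapiro", {"f": f, "k": k, "eps0": eps0}, r2, rmse, len(p), window)


def fit_heckel(curve: CompressionCurve, window=HECKEL_WINDOW) -> FitResult:
    """Heckel fit ln(1/ε) = kP + A; Py = 1/k is the mean yield pressure."""
    keep = _in_window(curve.pressure, window)
    p = curve.pressure[keep]
    eps = curve.porosity[keep]
    if len(p) < 3:
        return FitResult.failure("heckel", f"only {len(p)} points in window", window)
    y = np.log(1.0 / eps)
    res = stats.linregress(p, y)
    if res.slope <= 0:
        return FitResult.failure(
            "heckel", f"non-positive Heckel slope {res.slope:.3g}", window, n_points=len(p)
        )
    r2, rmse = _linear_diag(p, y, res.slope * p + res.intercept)
    return FitResult(
        "heckel",
        {"Py": 1.0 / res.slope, "A": res.intercept, "k": res.slope},
        r2,
        rmse,
        len(p),
        window,
    )


def fit_gurnham(curve: CompressionCurve, window=GURNHAM_WINDOW) -> FitResult:
    """Gurnham fit ε = −(1/K)·ln(P/P0); OLS of ε on ln P.

    K = −1/slope measures compressibility resistance; P0 = exp(intercept·K)
    is the extrapolated zero-porosity pressure.
    """
    keep = _in_window(curve.pressure, window)
    p = curve.pressure[keep]
    eps = curve.porosity[keep]
    if len(p) < 3:
        return FitResult.failure("gurnham", f"only {len(p)} points in window", window)
    res = stats.linregress(np.log(p), eps)
    if res.slope >= 0:
        return FitResult.failure(
            "gurnham", f"non-negative Gurnham slope {res.slope:.3g}", window, n_points=len(p)
        )
    big_k = -1.0 / res.slope
    p0 = math.exp(res.intercept * big_k)
    r2, rmse = _linear_diag(np.log(p), eps, res.slope * np.log(p) + res.intercept)
    return FitResult("gurnham", {"K": big_k, "P0": p0}, r2, rmse, len(p), window)


def fit_ryshkewitch_duckworth(curve: CompressionCurve, window=RD_WINDOW) -> FitResult:
    """Ryshkewitch–Duckworth fit ln TS = ln TS0 − kb·ε.

    kb is the bonding-capacity constant (larger = weaker bonding); TS0 the
    extrapolated zero-porosity strength.  Points with TS <= 0 are excluded.
    """
    keep = _in_window(curve.pressure, window)
    eps = curve.porosity[keep]
    ts = curve.tensile_strength[keep]
    positive = ts > 0
    if not np.all(positive):
        warnings.warn(
            f"{curve.material_id}/{curve.form}: excluded "
            f"{int(np.sum(~positive))} point(s) with TS <= 0",
            stacklevel=2,
        )
    eps, ts = eps[positive], ts[positive]
    if len(ts) < 3:
        return FitResult.failure("ryshkewitch_duckworth", f"only {len(ts)} usable points", window)
    y = np.log(ts)
    res = stats.linregress(eps, y)
    r2, rmse = _linear_diag(eps, y, res.slope * eps + res.intercept)
    return FitResult(
        "ryshkewitch_duckworth",
        {"kb": -res.slope, "TS0": math.exp(res.intercept)},
        r2,
        rmse,
        len(ts),
        window,
    )


def fit_power(curve: CompressionCurve, window=POWER_WINDOW, method="loglog") -> FitResult:
    """Tabletability fit TS = d·P^g.

    ``method='loglog'`` (default) is OLS of ln TS on ln P with R² on the
    log scale; ``method='nls'`` is a direct nonlinear least squares on the
    original scale (used as a cross-check oracle).  RMSE is always reported
    on the original TS scale.
    """
    keep = _in_window(curve.pressure, window)
    p = curve.pressure[keep]
    ts = curve.tensile_strength[keep]
    positive = ts > 0
    if not np.all(positive):
        warnings.warn(
            f"{curve.material_id}/{curve.form}: excluded "
            f"{int(np.sum(~positive))} point(s) with TS <= 0",
            stacklevel=2,
        )
    p, ts = p[positive], ts[positive]
    if len(p) < 3:
        return FitResult.failure("power", f"only {len(p)} usable points in window", window)
    if method == "loglog":
        res = stats.linregress(np.log(p), np.log(ts))
        d, g = math.exp(res.intercept), res.slope
        r2, _ = _linear_diag(np.log(p), np.log(ts), res.slope * np.log(p) + res.intercept)
    elif method == "nls":
        res_lin = stats.linregress(np.log(p), np.log(ts))
        try:
            (d, g), _ = optimize.curve_fit(
                lambda pp, dd, gg: dd * pp**gg,
                p,
                ts,
                p0=[math.exp(res_lin.intercept), res_lin.slope],
                maxfev=10_000,
            )
        except RuntimeError as exc:  # pragma: no cover - degenerate data
            return FitResult.failure("power", f"nonlinear fit failed: {exc}", window, len(p))
        ss_res = float(np.sum((ts - d * p**g) ** 2))
        ss_tot = float(np.sum((ts - np.mean(ts)) ** 2))
        r2 = 1.0 if ss_tot == 0 and ss_res < 1e-20 else 1.0 - ss_res / ss_tot
    else:
        raise ValueError(f"unknown power-fit method {method!r}")
    rmse = math.sqrt(float(np.mean((ts - d * p**g) ** 2)))
    return FitResult("power", {"d": d, "g": g}, r2, rmse, len(p), window)


def fit_all(curve: CompressionCurve, power_method="loglog") -> CBCSParameters:
    """Run all six model fits over their windows and assemble the CBCS set.

    Individual fit failures are carried as values (NaN parameters); only a
    curve on which every single model fails raises.
    """
    fits = {
        "kawakita": fit_kawakita(curve),
        "shapiro": fit_shapiro(curve),
        "heckel": fit_heckel(curve),
        "gurnham": fit_gurnham(curve),
        "ryshkewitch_duckworth": fit_ryshkewitch_duckworth(curve),
        "power": fit_power(curve, method=power_method),
    }
    if not any(fit.ok for fit in fits.values()):
        raise RuntimeError(
            f"{curve.material_id}/{curve.form}: all six compression model fits failed"
        )
    out = CBCSParameters(material_id=curve.material_id, form=curve.form, fits=fits)
    if fits["kawakita"].ok:
        out.a = fits["kawakita"].params["a"]
        out.b = fits["kawakita"].params["b"]
        out.ab = fits["kawakita"].params["ab"]
        out.b_inv = fits["kawakita"].params["b_inv"]
    if fits["shapiro"].ok:
        out.f = fits["shapiro"].params["f"]
        out.k_shapiro = fits["shapiro"].params["k"]
    if fits["heckel"].ok:
        out.Py = fits["heckel"].params["Py"]
        out.heckel_A = fits["heckel"].params["A"]
    if fits["gurnham"].ok:
        out.K = fits["gurnham"].params["K"]
        out.P0 = fits["gurnham"].params["P0"]
    if fits["ryshkewitch_duckworth"].ok:
        out.kb = fits["ryshkewitch_duckworth"].params["kb"]
        out.TS0 = fits["ryshkewitch_duckworth"].params["TS0"]
    if fits["power"].ok:
        out.d = fits["power"].params["d"]
        out.g = fits["power"].params["g"]
    return out
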