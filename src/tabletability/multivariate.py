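"""Multivariate stage: autoscaling, PCA, score ellipses, the data-fusion
design and PLS2 regression with cross-validated Q².

All decompositions operate on autoscaled (mean 0, unit variance, ddof=1)
matrices.  Component signs follow a fixed convention — the entry of each
loading vector with the largest magnitude is made positive — so scores,
loadings and regression diagnostics are reproducible run to run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .mechanics import compaction_pressure

__all__ = [
    "Scaler",
    "autoscale",
    "PCAResult",
    "pca",
    "HotellingEllipse",
    "hotelling_ellipse",
    "FusionDesign",
    "build_fusion_design",
    "PLS2Result",
    "pls2_fit",
    "q2_crossval",
    "FUSION_X_COLUMNS",
]

DEFAULT_FUSION_FORCES_KN = (3.0, 5.0, 7.0, 9.0, 11.0)

#: The 31 input columns of the data-fusion design: 19 physical properties,
#: 9 CBCS parameters, the two tabletability-change indices, and pressure.
PROPERTY_COLUMNS = [
    "D10_um",
    "D50_um",
    "D90_um",
    "span",
    "pct_Pf",
    "I_theta",
    "Da_g_mL",
    "Dc_g_mL",
    "Dt_g_cm3",
    "SFp",
    "eps_p",
    "IH",
    "IC",
    "Ie",
    "t_flow_min",
    "AOR_deg",
    "pct_H",
    "pct_HR",
    "Icd_N",
]
CBCS_COLUMNS = ["a", "b_inv", "ab", "f", "Py", "K", "kb", "d", "g"]
FUSION_X_COLUMNS = PROPERTY_COLUMNS + CBCS_COLUMNS + ["RP_percent", "CoTr_percent", "pressure_MPa"]


@dataclass(frozen=True)
class Scaler:
    mean: np.ndarray
    std: np.ndarray
    columns: tuple | None = None

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.std

    def inverse_transform(self, z):
        return np.asarray(z, dtype=float) * self.std + self.mean


def autoscale(x, columns=None):
    """Mean-center and scale to unit variance (sample, ddof=1) per column.

    Accepts a 2-D array or DataFrame; returns (scaled ndarray, Scaler).
    A zero-variance column is an error naming the column.
    """
    if isinstance(x, pd.DataFrame):
        columns = tuple(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("autoscale expects a 2-D matrix")
    if np.any(~np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    zero = std == 0
    if np.any(zero):
        names = (
            [columns[j] for j in np.flatnonzero(zero)]
            if columns is not None
            else list(np.flatnonzero(zero))
        )
        raise ValueError(f"zero-variance column(s): {names}")
    scaler = Scaler(mean=mean, std=std, columns=columns)
    return (x - mean) / std, scaler


@dataclass
class PCAResult:
    scores: np.ndarray  # n × k
    loadings: np.ndarray  # p × k, orthonormal columns
    explained_variance_ratio: np.ndarray
    columns: tuple | None = None

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        index = self.columns if self.columns is not None else None
        return pd.DataFrame(self.loadings, index=index, columns=cols)


def pca(x, n_components=None, columns=None) -> PCAResult:
    """PCA of an autoscaled matrix with a deterministic sign convention.

    ``x`` must already be scaled (use :func:`autoscale`).  Components are
    ordered by decreasing explained variance; each loading vector is
    flipped so its largest-magnitude entry is positive.  Degenerate rank
    is handled by truncating to the available rank.
    """
    if isinstance(x, pd.DataFrame):
        columns = tuple(x.columns)
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds max rank {max_rank}")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_.T  # p × k, unit-norm columns
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        columns=columns,
    )


@dataclass(frozen=True)
class HotellingEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float  # orientation of the major axis
    confidence: float
    degenerate: bool = False


def hotelling_ellipse(scores, confidence=0.95) -> HotellingEllipse:
    """Hotelling T² confidence ellipse for a group's 2-D scores.

    Uses the prediction-region scaling for a new observation,
    c = 2(n−1)(n+1)/(n(n−2)) · F(confidence; 2, n−2), so for large groups
    roughly ``confidence`` of same-population points fall inside.  A
    singular score covariance yields a degenerate (flagged) ellipse.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("hotelling_ellipse expects an n × 2 score matrix")
    n = scores.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points per group, got {n}")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    degenerate = bool(eigval[-1] <= 1e-12 * max(eigval[0], 1.0))
    c = 2.0 * (n - 1) * (n + 1) / (n * (n - 2)) * stats.f.ppf(confidence, 2, n - 2)
    semi = np.sqrt(np.clip(eigval, 0.0, None) * c)
    angle = math.atan2(eigvec[1, 0], eigvec[0, 0])
    return HotellingEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_rad=angle,
        confidence=confidence,
        degenerate=degenerate,
    )


@dataclass
class FusionDesign:
    """Input block X (materials × pressures rows, 31 columns) and response
    block Y (TS1 = powder tablet strength, TS2 = granule tablet strength)."""

    X: pd.DataFrame
    Y: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def build_fusion_design(
    properties: pd.DataFrame,
    cbcs: pd.DataFrame,
    indices: pd.DataFrame,
    forces_kn=DEFAULT_FUSION_FORCES_KN,
    punch_diameter_mm=10.0,
) -> FusionDesign:
    """Assemble the PLS2 data-fusion design.

    ``properties``: one row per material with the 19 powder physical
    property columns plus ``material_id``.  ``cbcs``: per material × form
    rows with the 9 CBCS parameter columns plus ``material_id``/``form``
    (the powder rows supply the X block; both forms must carry a power
    fit).  ``indices``: per material ``RP_percent``/``CoTr_percent``.

    Each compression force is converted to pressure; TS1/TS2 are evaluated
    from the powder/granule power fits at those pressures; per-material
    covariates replicate across the material's rows.  Materials missing a
    power fit are excluded with a warning entry.
    """
    pressures = np.array([compaction_pressure(f, punch_diameter_mm) for f in forces_kn])
    powder = cbcs[cbcs["form"] == "powder"].set_index("material_id")
    granule = cbcs[cbcs["form"] == "granule"].set_index("material_id")
    props = properties.set_index("material_id")
    idx = indices.set_index("material_id")

    rows_x, rows_y, row_labels, excluded = [], [], [], []
    for material_id in props.index:
        ok = (
            material_id in powder.index
            and material_id in granule.index
            and material_id in idx.index
            and np.isfinite(powder.loc[material_id, "d"])
            and np.isfinite(granule.loc[material_id, "d"])
        )
        if not ok:
            excluded.append(material_id)
            continue
        dp, gp = powder.loc[material_id, "d"], powder.loc[material_id, "g"]
        dg, gg = granule.loc[material_id, "d"], granule.loc[material_id, "g"]
        base = (
            [props.loc[material_id, c] for c in PROPERTY_COLUMNS]
            + [powder.loc[material_id, c] for c in CBCS_COLUMNS]
            + [idx.loc[material_id, "RP_percent"], idx.loc[material_id, "CoTr_percent"]]
        )
        for p in pressures:
            rows_x.append(base + [p])
            rows_y.append([dp * p**gp, dg * p**gg])
            row_labels.append(f"{material_id}@{p:.2f}MPa")
    x = pd.DataFrame(rows_x, columns=FUSION_X_COLUMNS, index=row_labels)
    y = pd.DataFrame(rows_y, columns=["TS1_MPa", "TS2_MPa"], index=row_labels)
    return FusionDesign(X=x, Y=y, excluded=excluded)


@dataclass
class PLS2Result:
    n_lv: int
    x_weights: np.ndarray  # p × A
    x_loadings: np.ndarray  # p × A
    y_loadings: np.ndarray  # m × A
    x_scores: np.ndarray  # n × A
    r2x_cum: np.ndarray
    r2y_cum: np.ndarray

    def coefficients(self, n_lv=None) -> np.ndarray:
        """Regression coefficients B (p × m) on the scaled space using the
        first ``n_lv`` latent variables: B = W (PᵀW)⁻¹ Qᵀ."""
        a = self.n_lv if n_lv is None else n_lv
        w = self.x_weights[:, :a]
        p = self.x_loadings[:, :a]
        q = self.y_loadings[:, :a]
        return w @ np.linalg.solve(p.T @ w, q.T)

    def predict(self, x_scaled, n_lv=None) -> np.ndarray:
        return np.asarray(x_scaled, dtype=float) @ self.coefficients(n_lv)


def pls2_fit(x, y, n_lv, tol=1e-10, max_iter=5000) -> PLS2Result:
    """NIPALS PLS2 on autoscaled X (n × p) and Y (n × m).

    One latent variable at a time: the X weight vector is iterated against
    a Y score until the relative X-score change falls below ``tol`` (the
    iteration cap is generous because nearly degenerate latent directions
    converge slowly); X is deflated
    by its rank-one reconstruction after each LV (Y is residualised only
    for the cumulative R²Y diagnostic).  Successive X scores are mutually
    orthogonal.  Non-convergence raises, naming the latent variable.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    if n_lv > min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} exceeds the rank bound {min(n - 1, p)}")
    ssx_tot = float(np.sum(x**2))
    ssy_tot = float(np.sum(y**2))
    xr, yr = x.copy(), y.copy()
    ws, ps, qs, ts = [], [], [], []
    r2x_cum, r2y_cum = [], []
    for a in range(n_lv):
        u = yr[:, int(np.argmax(np.sum(yr**2, axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = xr.T @ u / (u @ u)
            norm = np.linalg.norm(w)
            if norm == 0:
                raise RuntimeError(f"LV {a + 1}: X residual is orthogonal to Y")
            w /= norm
            t = xr @ w
            q = yr.T @ t / (t @ t)
            u = yr @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * max(
                np.linalg.norm(t), 1.0
            ):
                break
            t_old = t
        else:
            raise RuntimeError(f"NIPALS did not converge for latent variable {a + 1}")
        pvec = xr.T @ t / (t @ t)
        # deterministic sign: largest-|weight| entry positive
        i = int(np.argmax(np.abs(w)))
        if w[i] < 0:
            w, t, pvec, q = -w, -t, -pvec, -q
        xr = xr - np.outer(t, pvec)
        yr = yr - np.outer(t, q)
        ws.append(w)
        ps.append(pvec)
        qs.append(q)
        ts.append(t)
        r2x_cum.append(1.0 - float(np.sum(xr**2)) / ssx_tot)
        r2y_cum.append(1.0 - float(np.sum(yr**2)) / ssy_tot)
    return PLS2Result(
        n_lv=n_lv,
        x_weights=np.column_stack(ws),
        x_loadings=np.column_stack(ps),
        y_loadings=np.column_stack(qs),
        x_scores=np.column_stack(ts),
        r2x_cum=np.array(r2x_cum),
        r2y_cum=np.array(r2y_cum),
    )


def _fold_indices(n, n_folds, assignment="roundrobin", rng=None):
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds {n} rows")
    if assignment == "roundrobin":
        labels = np.arange(n) % n_folds
    elif assignment == "random":
        if rng is None:
            raise ValueError("random fold assignment needs an rng")
        labels = rng.permutation(np.arange(n) % n_folds)
    else:
        raise ValueError(f"unknown fold assignment {assignment!r}")
    return labels


def q2_crossval(x, y, max_lv, n_folds=7, assignment="roundrobin", rng=None):
    """Cumulative Q² per latent-variable count by k-fold cross-validation.

    Fold membership is deterministic round-robin over row order (a seeded
    random assignment is available).  Scaling parameters are re-estimated
    on each training fold; PRESS pools every Y column in original units and
    Q²cum(A) = 1 − PRESS(A)/SS with SS the total (column-mean-centred) sum
    of squares of Y.  A fold whose training part has < 2 rows is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    labels = _fold_indices(n, n_folds, assignment, rng)
    press = np.zeros(max_lv)
    for fold in range(n_folds):
        test = labels == fold
        train = ~test
        if int(np.sum(train)) < 2:
            raise ValueError(f"fold {fold}: training part has < 2 rows")
        xs_train, x_scaler = autoscale(x[train])
        ys_train, y_scaler = autoscale(y[train])
        fit = pls2_fit(xs_train, ys_train, max_lv)
        xs_test = x_scaler.transform(x[test])
        for a in range(1, max_lv + 1):
            pred = y_scaler.inverse_transform(fit.predict(xs_test, n_lv=a))
            press[a - 1] += float(np.sum((y[test] - pred) ** 2))
    ss = float(np.sum((y - y.mean(axis=0)) ** 2))
    return 1.0 - press / ss
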