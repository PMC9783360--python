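"""End-to-end library run: mechanics → model fits → envelope → change
indices → classification → multivariate stage.

Per-material failures are carried as values (NaN parameter rows, excluded
fusion rows) so a library run always completes; the manifest records what
was skipped.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .change import (
    auc_power,
    auc_trapezoid,
    change_indices,
    library_envelope,
)
from .classify import classify_cbcs, classify_tccs, downgrade_report
from .config import RunConfig
from .mechanics import aggregate_replicates, process_tablets
from .models import CompressionCurve, fit_all
from .multivariate import (
    CBCS_COLUMNS,
    autoscale,
    build_fusion_design,
    pca,
    pls2_fit,
    q2_crossval,
)
from .readwrite import densities_from_materials, write_csv

_MODEL_NAMES = ["kawakita", "shapiro", "heckel", "gurnham", "ryshkewitch_duckworth", "power"]


@dataclass
class PipelineResult:
    states: pd.DataFrame
    curves: list
    cbcs: pd.DataFrame
    indices: pd.DataFrame
    classification: pd.DataFrame
    pca_properties: object | None
    pca_cbcs: object | None
    pls: object | None
    pls_summary: pd.DataFrame | None
    fusion: object | None
    envelope: object | None
    manifest: dict = field(default_factory=dict)
    n_fits_attempted: int = 0


def build_curves(aggregated: pd.DataFrame, densities: dict) -> list[CompressionCurve]:
    """Assemble one CompressionCurve per material × form from aggregated states."""
    curves = []
    for (material_id, form), group in aggregated.groupby(["material_id", "form"], sort=True):
        density = densities[(material_id, form)]
        try:
            curves.append(
                CompressionCurve(
                    material_id=material_id,
                    form=form,
                    pressure=group["pressure_MPa"].to_numpy(),
                    porosity=group["porosity"].to_numpy(),
                    tensile_strength=group["tensile_strength_MPa"].to_numpy(),
                    bulk_density=density.bulk_density,
                    true_density=density.true_density,
                )
            )
        except ValueError as exc:
            warnings.warn(f"skipping curve {material_id}/{form}: {exc}", stacklevel=2)
    return curves


def _cbcs_table(results) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {
            "material_id": res.material_id,
            "form": res.form,
            "a": res.a,
            "b": res.b,
            "b_inv": res.b_inv,
            "ab": res.ab,
            "f": res.f,
            "k_shapiro": res.k_shapiro,
            "Py": res.Py,
            "heckel_A": res.heckel_A,
            "K": res.K,
            "P0": res.P0,
            "kb": res.kb,
            "TS0": res.TS0,
            "d": res.d,
            "g": res.g,
        }
        for name in _MODEL_NAMES:
            fit = res.fits[name]
            row[f"r2_{name}"] = fit.r2
            row[f"rmse_{name}"] = fit.rmse
            row[f"window_{name}"] = f"{fit.window[0]:g}-{fit.window[1]:g}"
            row[f"ok_{name}"] = fit.ok
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    materials: pd.DataFrame,
    tablets: pd.DataFrame,
    config: RunConfig | None = None,
    outdir=None,
    input_paths=(),
) -> PipelineResult:
    """Execute every stage on in-memory tables; optionally write the CSVs."""
    config = config or RunConfig()
    if len(tablets) == 0:
        raise ValueError("tablet table is empty; nothing to fit")
    densities = densities_from_materials(materials)
    missing = {
        (m, f) for m, f in zip(tablets["material_id"], tablets["form"])
    } - set(densities)
    if missing:
        raise ValueError(f"tablets reference materials without property rows: {sorted(missing)}")

    # 1) tablet mechanics
    states = process_tablets(
        tablets, densities, config.punch_diameter_mm, config.dense_tolerance
    )
    usable = states[~states["suspect"]] if config.exclude_suspect else states
    aggregated = aggregate_replicates(usable, config.aggregation)

    # 2) compression-model fits
    curves = build_curves(aggregated, densities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = [fit_all(curve, power_method=config.power_method) for curve in curves]
    cbcs = _cbcs_table(results)
    n_fits_attempted = 6 * len(curves)

    # 3) tabletability AUCs and the library envelope
    aucs = {}
    for curve, res in zip(curves, results):
        key = (res.material_id, res.form)
        if config.auc_method == "analytic_power" and np.isfinite(res.d):
            aucs[key] = auc_power(res.d, res.g, config.auc_window)
        elif config.auc_method == "trapezoid":
            aucs[key] = auc_trapezoid(
                curve.pressure, curve.tensile_strength, config.auc_window
            )
    envelope = library_envelope(list(aucs.values())) if len(aucs) >= 2 else None

    # 4) change indices + classification
    index_rows, class_rows = [], []
    material_ids = sorted({m for m, _ in aucs})
    for material_id in material_ids:
        if (material_id, "powder") not in aucs or (material_id, "granule") not in aucs:
            continue
        idx = change_indices(
            material_id, aucs[(material_id, "powder")], aucs[(material_id, "granule")], envelope
        )
        index_rows.append(
            {
                "material_id": material_id,
                "AUCp": idx.auc_p,
                "AUCg": idx.auc_g,
                "RP_percent": idx.rp_percent,
                "Ct": idx.ct,
                "CoTr_percent": idx.cotr_percent,
                "method": config.auc_method,
                "window_lo_MPa": config.auc_window[0],
                "window_hi_MPa": config.auc_window[1],
                "AUCmax": envelope.auc_max,
                "AUCmin": envelope.auc_min,
            }
        )
        sub = cbcs.set_index(["material_id", "form"])
        powder_fit = sub.loc[(material_id, "powder")]
        granule_fit = sub.loc[(material_id, "granule")]
        if not (np.isfinite(powder_fit["d"]) and np.isfinite(granule_fit["d"])):
            continue
        cat_p = classify_cbcs(
            powder_fit["d"], powder_fit["g"], config.acceptable_ts_mpa, config.good_ts_mpa
        )
        cat_g = classify_cbcs(
            granule_fit["d"], granule_fit["g"], config.acceptable_ts_mpa, config.good_ts_mpa
        )
        report = downgrade_report(cat_p.category, cat_g.category)
        class_rows.append(
            {
                "material_id": material_id,
                "powder_category": cat_p.category.value,
                "granule_category": cat_g.category.value,
                "downgrade_flag": report.is_downgrade,
                "CoTr_percent": idx.cotr_percent,
                "tccs_type": classify_tccs(idx.cotr_percent).value,
            }
        )
    indices = pd.DataFrame(index_rows)
    classification = pd.DataFrame(class_rows)

    # 5) multivariate stage
    pca_props = pca_cbcs_res = pls = fusion = None
    pls_summary = None
    prop_cols = [c for c in materials.columns if c not in ("material_id", "form", "material_class", "name")]
    if len(materials) >= 4:
        scaled, _ = autoscale(materials[prop_cols])
        pca_props = pca(scaled, n_components=min(3, len(materials) - 1), columns=tuple(prop_cols))
    cbcs_block = cbcs.dropna(subset=CBCS_COLUMNS)
    if len(cbcs_block) >= 4:
        scaled, _ = autoscale(cbcs_block[CBCS_COLUMNS])
        pca_cbcs_res = pca(scaled, n_components=min(3, len(cbcs_block) - 1), columns=tuple(CBCS_COLUMNS))
    powder_props = materials[materials["form"] == "powder"]
    if len(indices) >= 3 and len(powder_props) >= 3:
        fusion = build_fusion_design(
            powder_props[["material_id"] + prop_cols],
            cbcs,
            indices,
            forces_kn=config.fusion_forces_kn,
            punch_diameter_mm=config.punch_diameter_mm,
        )
        xs, _ = autoscale(fusion.X)
        ys, _ = autoscale(fusion.Y)
        n_lv = min(config.n_latent_variables, xs.shape[0] - 1, xs.shape[1])
        pls = pls2_fit(xs, ys, n_lv=n_lv)
        q2 = q2_crossval(
            fusion.X.to_numpy(), fusion.Y.to_numpy(), max_lv=n_lv, n_folds=config.cv_folds
        )
        pls_summary = pd.DataFrame(
            {
                "LV": np.arange(1, n_lv + 1),
                "R2X_cum": pls.r2x_cum,
                "R2Y_cum": pls.r2y_cum,
                "Q2_cum": q2,
            }
        )

    manifest = {
        "software": {"name": "tabletability", "version": __version__},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "inputs": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in input_paths
        },
        "envelope": None
        if envelope is None
        else {"AUCmax": envelope.auc_max, "AUCmin": envelope.auc_min, "Amax": envelope.a_max},
        "n_curves": len(curves),
        "n_fits_attempted": n_fits_attempted,
        "n_fits_ok": int(sum(res.n_ok for res in results)),
        "n_materials_indexed": len(indices),
    }

    result = PipelineResult(
        states=states,
        curves=curves,
        cbcs=cbcs,
        indices=indices,
        classification=classification,
        pca_properties=pca_props,
        pca_cbcs=pca_cbcs_res,
        pls=pls,
        pls_summary=pls_summary,
        fusion=fusion,
        envelope=envelope,
        manifest=manifest,
        n_fits_attempted=n_fits_attempted,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(result.cbcs, outdir / "cbcs_params.csv")
    write_csv(result.indices, outdir / "change_indices.csv")
    write_csv(result.classification, outdir / "classification.csv")
    if result.pls_summary is not None:
        write_csv(result.pls_summary, outdir / "pls_summary.csv")
    if result.pls is not None and result.fusion is not None:
        loadings = pd.DataFrame(
            result.pls.x_loadings,
            index=result.fusion.X.columns,
            columns=[f"LV{i + 1}" for i in range(result.pls.n_lv)],
        )
        loadings.index.name = "variable"
        loadings.reset_index().to_csv(outdir / "pls_loadings.csv", index=False)
    pca_info = {}
    for name, res in (("pca_properties", result.pca_properties), ("pca_cbcs", result.pca_cbcs)):
        if res is not None:
            frame = res.loadings_frame()
            frame.index.name = "variable"
            frame.reset_index().to_csv(outdir / f"{name}_loadings.csv", index=False)
            pca_info[name] = {
                "explained_variance_ratio": [float(v) for v in res.explained_variance_ratio]
            }
    if pca_info:
        with open(outdir / "pca_summary.json", "w", encoding="utf-8") as fh:
            json.dump(pca_info, fh, indent=2, sort_keys=True)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return outdir
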