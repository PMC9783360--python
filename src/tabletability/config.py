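"""Run configuration with the study defaults, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    """All tunable knobs of a library run.

    Defaults reproduce the study conditions: a 10 mm flat punch, model
    windows of 10–140 MPa (Shapiro 0–50 MPa), analytic power-curve AUC over
    10–140 MPa, TS thresholds of 2 MPa (acceptable) and 3 MPa (good),
    mean replicate aggregation and 7-fold round-robin cross-validation.
    """

    punch_diameter_mm: float = 10.0
    aggregation: str = "mean"  # mean | median
    dense_tolerance: float = 0.02
    exclude_suspect: bool = False
    model_window: tuple[float, float] = (10.0, 140.0)
    shapiro_window: tuple[float, float] = (0.0, 50.0)
    auc_window: tuple[float, float] = (10.0, 140.0)
    auc_method: str = "analytic_power"  # analytic_power | trapezoid
    power_method: str = "loglog"  # loglog | nls
    acceptable_ts_mpa: float = 2.0
    good_ts_mpa: float = 3.0
    fusion_forces_kn: tuple[float, ...] = (3.0, 5.0, 7.0, 9.0, 11.0)
    n_latent_variables: int = 5
    cv_folds: int = 7
    # simulation only
    n_materials: int = 29
    noise_sd: float = 0.01
    replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("model_window", "shapiro_window", "auc_window"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} is degenerate: {(lo, hi)}")
        if self.aggregation not in ("mean", "median"):
            raise ValueError(f"aggregation must be mean or median, got {self.aggregation!r}")
        if self.auc_method not in ("analytic_power", "trapezoid"):
            raise ValueError(f"unknown auc_method {self.auc_method!r}")
        if not self.good_ts_mpa >= self.acceptable_ts_mpa:
            raise ValueError("good TS threshold must be >= acceptable threshold")

    def to_dict(self) -> dict:
        out = asdict(self)
        for key, value in out.items():
            if isinstance(value, tuple):
                out[key] = list(value)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(data)
        for name in ("model_window", "shapiro_window", "auc_window", "fusion_forces_kn"):
            if name in coerced:
                coerced[name] = tuple(coerced[name])
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
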