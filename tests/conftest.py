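import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tabletability.config import RunConfig
from tabletability.models import CompressionCurve
from tabletability.pipeline import run_pipeline
from tabletability.simulate import library_tables, make_library

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

FULL_GRID = np.array([10.0, 25.0, 40.0, 70.0, 105.0, 140.0])


def make_curve(pressure, porosity, ts, bulk_density=0.5, true_density=1.5,
               material_id="M", form="powder"):
    """Build a CompressionCurve from raw arrays (test helper)."""
    return CompressionCurve(
        material_id=material_id,
        form=form,
        pressure=np.asarray(pressure, dtype=float),
        porosity=np.asarray(porosity, dtype=float),
        tensile_strength=np.asarray(ts, dtype=float),
        bulk_density=bulk_density,
        true_density=true_density,
    )


def gurnham_porosity(pressure, K=10.0, P0=500.0):
    return -np.log(np.asarray(pressure, dtype=float) / P0) / K


def power_ts(pressure, d=0.1, g=0.7):
    return d * np.asarray(pressure, dtype=float) ** g


@pytest.fixture(scope="session")
def clean_library():
    """Zero-noise default 29-material library and its pipeline tables."""
    lib = make_library(seed=7, noise_sd=0.0)
    materials, tablets, truth = library_tables(lib)
    return lib, materials, tablets, truth


@pytest.fixture(scope="session")
def clean_result(clean_library):
    _, materials, tablets, _ = clean_library
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(materials, tablets, RunConfig())
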