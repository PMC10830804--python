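"""Shared fixtures: small generating models, fitted bundles, helpers.

Expensive fits (the 80-item preset at n = 10,000) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from ipvis.cfa import FitResult, fit_all
from ipvis.center_distance import build_estimates
from ipvis.naming import parse_columns
from ipvis.simulate import (
    GeneratingModel,
    hexaco_like_preset,
    population_fits,
    sample_dataset,
)


def make_fit_result(
    loadings: dict[str, tuple[str, float]],
    correlations: pd.DataFrame | None = None,
    model_level: str = "tests",
    n_used: int = 100,
) -> FitResult:
    """Hand-built FitResult with prescribed standardized loadings."""
    items = list(loadings)
    factors = []
    for _, (f, _lam) in loadings.items():
        if f not in factors:
            factors.append(f)
    if correlations is None:
        correlations = pd.DataFrame(
            np.eye(len(factors)), index=factors, columns=factors
        )
    frame = pd.DataFrame(
        {
            "factor": [loadings[c][0] for c in items],
            "loading": [loadings[c][1] for c in items],
            "loading_raw": [loadings[c][1] for c in items],
            "residual_variance": [1 - loadings[c][1] ** 2 for c in items],
        },
        index=pd.Index(items, name="item"),
    )
    return FitResult(
        model_level=model_level,
        loadings=frame,
        factor_correlations=correlations,
        n_used=n_used,
        converged=True,
        discrepancy_value=0.0,
        iterations=1,
    )


@pytest.fixture(scope="session")
def small_model() -> GeneratingModel:
    """2 tests x 2 facets x 3 items, pure simple structure, healthy loadings."""
    cols = [f"T{t}_F{t}{f}_i{i}" for t in (1, 2) for f in (1, 2) for i in (1, 2, 3)]
    rng = np.random.default_rng(42)
    loadings = {c: round(float(rng.uniform(0.55, 0.8)), 3) for c in cols}
    facets = ["F11", "F12", "F21", "F22"]
    Phi = np.array(
        [
            [1.0, 0.6, 0.30, 0.25],
            [0.6, 1.0, 0.25, 0.30],
            [0.30, 0.25, 1.0, 0.55],
            [0.25, 0.30, 0.55, 1.0],
        ]
    )
    return GeneratingModel(
        naming=parse_columns(cols, "P"),
        loadings=loadings,
        factor_correlations=pd.DataFrame(Phi, index=facets, columns=facets),
        n=2000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_pop_fits(small_model):
    return population_fits(small_model)


@pytest.fixture(scope="session")
def small_pop_bundle(small_model, small_pop_fits):
    return build_estimates(small_pop_fits, small_model.naming)


@pytest.fixture(scope="session")
def small_sample_bundle(small_model):
    data = sample_dataset(small_model)
    fits = fit_all(data, small_model.naming)
    return build_estimates(fits, small_model.naming)


@pytest.fixture(scope="session")
def preset_model() -> GeneratingModel:
    return hexaco_like_preset(seed=11, n=10_000)


@pytest.fixture(scope="session")
def preset_pop_bundle(preset_model):
    fits = population_fits(preset_model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_estimates(fits, preset_model.naming)


@pytest.fixture(scope="session")
def preset_sample_bundle(preset_model):
    data = sample_dataset(preset_model)
    fits = fit_all(data, preset_model.naming)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_estimates(fits, preset_model.naming)
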