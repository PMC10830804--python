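"""Synthetic item-response data with known factor structure.

A :class:`GeneratingModel` defines a population at the most specific naming
level (facets for three-part names, tests for two-part names): each item has
one primary loading on its own factor, optionally one small secondary
loading on another factor (to plant deliberately misfitting items), a valid
factor correlation matrix, and a residual variance that brings every item
variance to exactly 1.  Responses are multivariate normal in this unit
metric; missing values are injected completely at random.

The coarser layers of the hierarchy are not free parameters: the population
test-level and global-level loadings are *derived* by fitting the coarser
simple-structure models to the exact population covariance.  This makes the
"true" center distances of the generating model well-defined — they are the
values an infinite sample would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .cfa import FitOptions, FitResult, fit_model
from .naming import ItemNaming, ModelSpec, parse_columns, specify_models

__all__ = [
    "GeneratingModel",
    "population_covariance",
    "population_fits",
    "sample_dataset",
    "hexaco_like_preset",
]


@dataclass
class GeneratingModel:
    """Population model for synthetic item responses (unit item variances)."""

    naming: ItemNaming
    loadings: dict[str, float]
    """Primary loading of each item column on its own most-specific factor."""
    factor_correlations: pd.DataFrame
    """Correlations among the most-specific factors (facets, or tests for
    two-part naming)."""
    secondary_loadings: dict[str, tuple[str, float]] = field(default_factory=dict)
    """Optional item -> (other factor, loading): a planted cross-loading."""
    n: int = 1000
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        missing = [c for c in self.naming.columns if c not in self.loadings]
        if missing:
            raise ValueError(f"no loading given for items {missing}")
        Phi = self.factor_correlations.to_numpy()
        if not np.allclose(Phi, Phi.T) or not np.allclose(np.diag(Phi), 1.0):
            raise ValueError("factor_correlations must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(Phi).min() < -1e-10:
            raise ValueError("factor_correlations is not positive semi-definite")
        if (self.communalities() >= 1.0).any():
            bad = self.communalities()
            raise ValueError(
                "implied common variance >= 1 for items "
                f"{list(bad.index[bad >= 1.0])}; loadings too large for the "
                "unit-variance metric"
            )

    # -- structure ----------------------------------------------------------

    @property
    def generative_level(self) -> str:
        return "facets" if self.naming.has_facets else "tests"

    @property
    def specs(self) -> list[ModelSpec]:
        return specify_models(self.naming)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factor_correlations.columns)

    def loading_matrix(self) -> pd.DataFrame:
        """Full (items x factors) loading matrix, including secondaries."""
        spec = self.specs[-1]
        Lam = pd.DataFrame(
            0.0, index=self.naming.columns, columns=self.factor_names
        )
        for name, cols in spec.factors.items():
            for c in cols:
                Lam.loc[c, name] = self.loadings[c]
        for c, (fac, lam) in self.secondary_loadings.items():
            Lam.loc[c, fac] += lam
        return Lam

    def communalities(self) -> pd.Series:
        Lam = self.loading_matrix().to_numpy()
        Phi = self.factor_correlations.to_numpy()
        return pd.Series(
            np.einsum("if,fg,ig->i", Lam, Phi, Lam), index=self.naming.columns
        )

    def residual_variances(self) -> pd.Series:
        """Residuals bringing every item variance to exactly 1."""
        return 1.0 - self.communalities()

    def to_dict(self) -> dict:
        return {
            "columns": self.naming.columns,
            "pool_name": self.naming.pool_name,
            "separator": self.naming.separator,
            "loadings": {k: float(v) for k, v in self.loadings.items()},
            "secondary_loadings": {
                k: [f, float(v)] for k, (f, v) in self.secondary_loadings.items()
            },
            "factor_correlations": {
                "factors": self.factor_names,
                "matrix": self.factor_correlations.to_numpy().tolist(),
            },
            "n": self.n,
            "seed": self.seed,
            "missing_rate": self.missing_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingModel":
        naming = parse_columns(d["columns"], d["pool_name"], d.get("separator", "_"))
        names = d["factor_correlations"]["factors"]
        Phi = pd.DataFrame(
            np.asarray(d["factor_correlations"]["matrix"], dtype=float),
            index=names,
            columns=names,
        )
        return cls(
            naming=naming,
            loadings=d["loadings"],
            factor_correlations=Phi,
            secondary_loadings={
                k: (f, v) for k, (f, v) in d.get("secondary_loadings", {}).items()
            },
            n=int(d.get("n", 1000)),
            seed=int(d.get("seed", 0)),
            missing_rate=float(d.get("missing_rate", 0.0)),
        )


def population_covariance(model: GeneratingModel) -> pd.DataFrame:
    """Exact population covariance Sigma = Lambda Phi Lambda' + Theta."""
    Lam = model.loading_matrix().to_numpy()
    Phi = model.factor_correlations.to_numpy()
    Sigma = Lam @ Phi @ Lam.T
    Sigma[np.diag_indices_from(Sigma)] += model.residual_variances().to_numpy()
    cols = model.naming.columns
    return pd.DataFrame(Sigma, index=cols, columns=cols)


def population_fits(
    model: GeneratingModel, options: FitOptions | None = None
) -> list[FitResult]:
    """The model hierarchy fitted to the exact population covariance.

    This is the noise-free oracle: the most specific fit recovers the
    generating parameters exactly (up to optimizer tolerance) whenever the
    model has pure simple structure, and the coarser fits define the
    population-implied general loadings and hence the "true" center
    distances.  ``n_used`` is reported as 0 (no sampling involved).
    """
    Sigma = population_covariance(model)
    return [fit_model(Sigma, 0, spec, options) for spec in model.specs]


def sample_dataset(model: GeneratingModel) -> pd.DataFrame:
    """Draw ``model.n`` multivariate-normal responses, with MCAR missingness.

    Deterministic given ``model.seed``.
    """
    if model.n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed)
    Phi = model.factor_correlations.to_numpy()
    # eigendecomposition square root: tolerant of a PSD-but-singular Phi
    w, V = np.linalg.eigh(Phi)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)
    K = Phi.shape[0]
    factors = rng.standard_normal((model.n, K)) @ root.T
    Lam = model.loading_matrix().to_numpy()
    resid_sd = np.sqrt(model.residual_variances().to_numpy())
    p = Lam.shape[0]
    data = factors @ Lam.T + rng.standard_normal((model.n, p)) * resid_sd
    df = pd.DataFrame(data, columns=model.naming.columns)
    if model.missing_rate > 0:
        mask = rng.random(df.shape) < model.missing_rate
        df = df.mask(mask)
    return df


# ---------------------------------------------------------------------------
# HEXACO-like preset
# ---------------------------------------------------------------------------

_PRESET_TESTS = {
    "H": ["Sinc", "Fair", "Gree", "Mode"],
    "A": ["Forg", "Gent", "Flex", "Pati"],
}
_PRESET_TEST_CORRELATION = 0.45
_PRESET_WITHIN = 0.50  # within-test facet correlations
_OUTLIER_ITEM = "H_Sinc_Sinc10"
_OUTLIER_PRIMARY = 0.20
_OUTLIER_SECONDARY = ("Gent", -0.40)
# cross-test pattern multipliers: Gent is tied tightly to three H facets but
# only loosely to Sinc, which is what pulls the planted outlier's general
# loading negative without cancelling its facet loading; the high Fair-Gent
# pair also lands above the test correlation, giving the preset an xarrow
_PRESET_CROSS_PATTERN = {
    ("Sinc", "Gent"): 0.5,
    ("Fair", "Gent"): 1.8,
    ("Gree", "Gent"): 1.6,
    ("Mode", "Gent"): 1.6,
}


def _preset_phi(cross: float) -> pd.DataFrame:
    """Facet correlation matrix: fixed within-test block, scaled cross-test block."""
    facets = [f for fs in _PRESET_TESTS.values() for f in fs]
    K = len(facets)
    Phi = np.zeros((K, K))
    # mild within-test heterogeneity, symmetric and deterministic
    for t0 in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                Phi[t0 + i, t0 + j] = Phi[t0 + j, t0 + i] = _PRESET_WITHIN + 0.04 * (
                    (i + j) % 3 - 1
                )
    for i in range(4):
        for j in range(4, 8):
            mult = _PRESET_CROSS_PATTERN.get((facets[i], facets[j]), 1.0)
            Phi[i, j] = Phi[j, i] = cross * mult
    np.fill_diagonal(Phi, 1.0)
    return pd.DataFrame(Phi, index=facets, columns=facets)


def _preset_model(cross: float, n: int, seed: int, missing_rate: float) -> GeneratingModel:
    cols, loadings = [], {}
    rng = np.random.default_rng(20_14)  # fixed: the preset population is one object
    for test, facets in _PRESET_TESTS.items():
        for facet in facets:
            for i in range(1, 11):
                col = f"{test}_{facet}_{facet}{i}"
                cols.append(col)
                loadings[col] = round(float(rng.uniform(0.45, 0.80)), 3)
    loadings[_OUTLIER_ITEM] = _OUTLIER_PRIMARY
    naming = parse_columns(cols, "HA")
    return GeneratingModel(
        naming=naming,
        loadings=loadings,
        factor_correlations=_preset_phi(cross),
        secondary_loadings={_OUTLIER_ITEM: _OUTLIER_SECONDARY},
        n=n,
        seed=seed,
        missing_rate=missing_rate,
    )


@lru_cache(maxsize=1)
def _calibrated_cross() -> float:
    """Cross-test facet-correlation scale whose population-implied test
    correlation equals the preset's nominal 0.45, found by bisection on
    exact-population fits of the tests model."""
    def implied_r(cross: float) -> float:
        model = _preset_model(cross, n=1, seed=0, missing_rate=0.0)
        Sigma = population_covariance(model)
        fit = fit_model(Sigma, 0, model.specs[1])
        return fit.correlation("H", "A")

    lo, hi = 0.05, 0.48
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if implied_r(mid) < _PRESET_TEST_CORRELATION:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    return 0.5 * (lo + hi)


def hexaco_like_preset(
    seed: int = 0, n: int = 10_000, missing_rate: float = 0.0
) -> GeneratingModel:
    """A 2-test x 4-facet x 10-item generating model shaped like a pair of
    correlated personality trait scales.

    Heterogeneous facet loadings in [0.45, 0.80]; the cross-test facet
    correlations are calibrated so the population-implied test-level
    correlation is 0.45; one item (``H_Sinc_Sinc10``) is a planted outlier
    with a small primary loading and a small negative cross-loading on a
    facet of the other test, so that its general loading collapses toward
    zero while its facet loading stays small but positive — the classic
    misfitting-item signature that inflates the mean but not the aggregate
    center distance of its facet.
    """
    return _preset_model(_calibrated_cross(), n=n, seed=seed, missing_rate=missing_rate)
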