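"""End-to-end estimation: raw responses in, estimates bundle out.

:class:`ItemPoolVisualization` is the two-call workflow's first call as an
estimator: ``fit`` parses the naming convention from the column names,
derives the nested model hierarchy, fits every model by ML, and assembles
the center-distance bundle.  The second call is one of the chart functions
(:func:`ipvis.facet_chart`, :func:`ipvis.item_chart`,
:func:`ipvis.nested_chart`, :func:`ipvis.item_overview`) on ``estimates_``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .cfa import BaseEstimator, FitOptions, fit_model, prepare_covariance
from .center_distance import DEFAULT_CD_CAP, EstimatesBundle, build_estimates
from .exceptions import NamingFormatError
from .naming import parse_columns, specify_models

__all__ = ["ItemPoolVisualization", "estimate"]


class ItemPoolVisualization(BaseEstimator):
    """Fit the nested factor-model hierarchy and compute center distances.

    Parameters
    ----------
    pool_name : str
        Name of the total item pool (the global factor).
    separator : str
        Separator in the ``test_facet_item`` column names.
    missing : {"listwise", "pairwise"}
        Missing-data policy for the sample covariance.
    cd_method : {"aggregate", "mean"}
        Default sub-pool summary for charts.
    cd_cap : float
        Display cap for unbounded center distances (general loading ~ 0).
    max_iter, gtol : optimizer settings passed to every model fit.
    allow_unconverged : bool
        Build the bundle even if a model did not converge.

    Attributes
    ----------
    naming_ : ItemNaming
    model_specs_ : list of ModelSpec
    fits_ : list of FitResult (general to specific)
    estimates_ : EstimatesBundle
    n_used_ : int

    Examples
    --------
    >>> ipv = ItemPoolVisualization(pool_name="HA").fit(responses)
    >>> ipv.estimates_.global_table.summaries
    """

    def __init__(
        self,
        pool_name: str = "pool",
        separator: str = "_",
        missing: Literal["listwise", "pairwise"] = "listwise",
        cd_method: Literal["aggregate", "mean"] = "aggregate",
        cd_cap: float = DEFAULT_CD_CAP,
        max_iter: int = 10_000,
        gtol: float = 1e-8,
        allow_unconverged: bool = False,
    ):
        self.pool_name = pool_name
        self.separator = separator
        self.missing = missing
        self.cd_method = cd_method
        self.cd_cap = cd_cap
        self.max_iter = max_iter
        self.gtol = gtol
        self.allow_unconverged = allow_unconverged

    def fit(self, X: pd.DataFrame, y=None) -> "ItemPoolVisualization":
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a pandas DataFrame whose column names follow the "
                "'test_facet_item' / 'test_item' convention"
            )
        non_numeric = [
            c
            for c in X.columns
            if not pd.api.types.is_numeric_dtype(X[c])
        ]
        if non_numeric:
            raise NamingFormatError(
                f"non-numeric column(s) {non_numeric}; the data may not "
                "include any additional variables — every column is treated "
                "as an item"
            )
        self.naming_ = parse_columns(
            list(X.columns), self.pool_name, self.separator
        )
        self.model_specs_ = specify_models(self.naming_)
        cov, n_used = prepare_covariance(
            X[self.naming_.columns].astype(float), policy=self.missing
        )
        opts = FitOptions(max_iter=self.max_iter, gtol=self.gtol)
        self.fits_ = [fit_model(cov, n_used, spec, opts) for spec in self.model_specs_]
        self.n_used_ = n_used
        self.estimates_ = build_estimates(
            self.fits_,
            self.naming_,
            cd_method=self.cd_method,
            cap=self.cd_cap,
            allow_unconverged=self.allow_unconverged,
        )
        return self

    def transform(self, X=None) -> EstimatesBundle:
        """Return the fitted estimates bundle (ignores ``X``)."""
        if not hasattr(self, "estimates_"):
            raise AttributeError("not fitted yet; call fit(X) first")
        return self.estimates_


def estimate(
    data: pd.DataFrame,
    pool_name: str,
    **params,
) -> EstimatesBundle:
    """One-call estimation: the bundle from raw wide-format responses."""
    return ItemPoolVisualization(pool_name=pool_name, **params).fit(data).estimates_
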