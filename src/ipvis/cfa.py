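"""Maximum-likelihood confirmatory factor analysis on a covariance matrix.

Each model has simple structure (every item loads on exactly one factor),
freely correlated factors, and a diagonal residual covariance.  The model is
identified by fixing all factor variances to 1, so loadings and inter-factor
correlations are estimated directly and the completely standardized solution
is immediate.  The fit minimizes the normal-theory ML discrepancy

    F(theta) = ln det Sigma + tr(S Sigma^-1) - ln det S - p,
    Sigma    = Lambda Phi Lambda' + Theta,

over loadings Lambda, factor correlations Phi (unit diagonal) and residual
variances Theta (diagonal).  The optimizer works on an unconstrained
reparameterization: residual variances through their logarithm and the
correlation matrix through a row-normalized Cholesky factor, so every iterate
is admissible (Theta > 0, Phi a valid correlation matrix).  Analytic
gradients are supplied throughout.

Because the discrepancy is invariant under rescaling of the observed
variables, the optimization runs on the correlation scale of the input and
results are mapped back; standardized estimates do not depend on item units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize

from .exceptions import (
    DegenerateDataError,
    HeywoodWarning,
    InsufficientDataError,
    NotConvergedError,
)
from .naming import ItemNaming, ModelSpec, specify_models

__all__ = [
    "FitResult",
    "FitOptions",
    "prepare_covariance",
    "fit_model",
    "fit_all",
    "ConfirmatoryFactorAnalysis",
]


# ---------------------------------------------------------------------------
# covariance preparation
# ---------------------------------------------------------------------------

def prepare_covariance(
    data: pd.DataFrame,
    policy: Literal["listwise", "pairwise"] = "listwise",
) -> tuple[pd.DataFrame, int]:
    """Sample covariance matrix and effective sample size.

    ``listwise`` drops every row with any missing value and uses the
    ordinary (n-1)-denominator covariance.  ``pairwise`` computes each
    covariance from the complete pairs for that pair of columns and reports
    the smallest pair count as the effective n.
    """
    if data.shape[1] < 2:
        raise InsufficientDataError("need at least 2 item columns")
    if policy not in ("listwise", "pairwise"):
        raise ValueError(f"unknown missing-data policy {policy!r}")

    if policy == "listwise":
        complete = data.dropna(axis=0, how="any")
        n_used = int(len(complete))
        if n_used <= data.shape[1]:
            raise InsufficientDataError(
                f"only {n_used} complete rows for {data.shape[1]} items after "
                "listwise deletion"
            )
        cov = complete.cov()
    else:
        notna = data.notna().to_numpy(dtype=np.int64)
        pair_counts = notna.T @ notna
        n_used = int(pair_counts.min())
        if n_used <= data.shape[1]:
            raise InsufficientDataError(
                f"smallest complete-pair count is {n_used} for "
                f"{data.shape[1]} items under pairwise deletion"
            )
        cov = data.cov()  # pandas: pairwise complete observations

    variances = np.diag(cov.to_numpy())
    zero = [c for c, v in zip(cov.columns, variances) if not v > 0]
    if zero:
        raise DegenerateDataError(
            f"zero-variance column(s): {zero}; constant items carry no "
            "information for a factor model"
        )
    return cov, n_used


# ---------------------------------------------------------------------------
# fit result container
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Standardized solution of one fitted factor model."""

    model_level: str
    loadings: pd.DataFrame
    """Per item (index = column name): ``factor``, ``loading`` (standardized),
    ``loading_raw`` (on the input covariance scale), ``residual_variance``
    (standardized)."""
    factor_correlations: pd.DataFrame
    n_used: int
    converged: bool
    discrepancy_value: float
    iterations: int
    warnings: list[str] = field(default_factory=list)
    internal_x: np.ndarray | None = field(default=None, repr=False, compare=False)
    """Optimizer solution vector (correlation scale); usable as a warm start."""

    @property
    def factor_names(self) -> list[str]:
        return list(self.factor_correlations.columns)

    def loading_of(self, column: str) -> float:
        return float(self.loadings.loc[column, "loading"])

    def correlation(self, a: str, b: str) -> float:
        return float(self.factor_correlations.loc[a, b])

    def require_converged(self, allow_unconverged: bool = False) -> None:
        if not self.converged and not allow_unconverged:
            raise NotConvergedError(
                f"the {self.model_level} model did not converge; pass "
                "allow_unconverged=True to use its estimates anyway"
            )

    def to_dict(self) -> dict:
        return {
            "model_level": self.model_level,
            "loadings": {
                col: {
                    "factor": row["factor"],
                    "loading": float(row["loading"]),
                    "loading_raw": float(row["loading_raw"]),
                    "residual_variance": float(row["residual_variance"]),
                }
                for col, row in self.loadings.iterrows()
            },
            "factor_correlations": {
                "factors": self.factor_names,
                "matrix": self.factor_correlations.to_numpy().tolist(),
            },
            "n_used": self.n_used,
            "converged": self.converged,
            "discrepancy_value": self.discrepancy_value,
            "iterations": self.iterations,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        load = pd.DataFrame.from_dict(d["loadings"], orient="index")
        load = load[["factor", "loading", "loading_raw", "residual_variance"]]
        names = d["factor_correlations"]["factors"]
        corr = pd.DataFrame(
            np.asarray(d["factor_correlations"]["matrix"], dtype=float),
            index=names,
            columns=names,
        )
        return cls(
            model_level=d["model_level"],
            loadings=load,
            factor_correlations=corr,
            n_used=int(d["n_used"]),
            converged=bool(d["converged"]),
            discrepancy_value=float(d["discrepancy_value"]),
            iterations=int(d["iterations"]),
            warnings=list(d.get("warnings", [])),
        )


@dataclass
class FitOptions:
    """Optimizer settings for one model fit."""

    max_iter: int = 10_000
    gtol: float = 1e-8
    start_loading: float = 0.7
    start_residual: float = 0.51
    start_correlation: float = 0.3
    heywood_tol: float = 1e-6
    x0: np.ndarray | None = None
    """Warm-start vector (e.g. a previous fit's ``internal_x``); overrides
    the generic start values."""


# ---------------------------------------------------------------------------
# the ML discrepancy and its gradient
# ---------------------------------------------------------------------------

class _MLProblem:
    """ML discrepancy on the correlation scale for one simple-structure model.

    Parameter vector layout: p loadings, p log residual variances, then the
    K(K-1)/2 free entries of a row-normalized Cholesky factor of Phi
    (row i of the lower-triangular matrix L has L[i, i] = 1 and free entries
    L[i, :i]; the unit-normalized rows C = L / ||L_i|| give Phi = C C').
    """

    def __init__(self, R: np.ndarray, factor_index: np.ndarray, n_factors: int):
        self.R = R
        self.p = R.shape[0]
        self.K = n_factors
        self.f = factor_index  # item -> factor index
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0:
            raise DegenerateDataError(
                "the sample correlation matrix is singular or indefinite; "
                "the ML discrepancy is undefined"
            )
        self.logdet_S = logdet
        self.n_corr = n_factors * (n_factors - 1) // 2
        self.tril_rows, self.tril_cols = np.tril_indices(n_factors, k=-1)

    # -- parameter packing ---------------------------------------------------

    def pack(self, lam: np.ndarray, theta: np.ndarray, L: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [lam, np.log(theta), L[self.tril_rows, self.tril_cols]]
        )

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p, K = self.p, self.K
        lam = x[:p]
        theta = np.exp(x[p : 2 * p])
        L = np.eye(K)
        L[self.tril_rows, self.tril_cols] = x[2 * p :]
        return lam, theta, L

    def phi_of(self, L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        norms = np.sqrt((L**2).sum(axis=1))
        C = L / norms[:, None]
        return C @ C.T, C, norms

    # -- objective -----------------------------------------------------------

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        p, K = self.p, self.K
        lam, theta, L = self.unpack(x)
        Phi, C, norms = self.phi_of(L)

        Lam = np.zeros((p, K))
        Lam[np.arange(p), self.f] = lam
        Sigma = Lam @ Phi @ Lam.T
        Sigma[np.diag_indices(p)] += theta

        try:
            cf = sla.cho_factor(Sigma, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(x)
        logdet_Sigma = 2.0 * np.log(np.diag(cf[0])).sum()
        Sigma_inv = sla.cho_solve(cf, np.eye(p), check_finite=False)
        SinvS = Sigma_inv @ self.R
        F = logdet_Sigma + np.trace(SinvS) - self.logdet_S - p
        if not np.isfinite(F):
            return np.inf, np.zeros_like(x)

        # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1
        G = Sigma_inv - SinvS @ Sigma_inv
        G = 0.5 * (G + G.T)

        GLP = G @ Lam @ Phi
        g_lam = 2.0 * GLP[np.arange(p), self.f]
        g_logtheta = np.diag(G) * theta

        if self.n_corr:
            M = Lam.T @ G @ Lam  # dF/dPhi contribution, symmetric
            MC = M @ C
            # chain through C_i = L_i/||L_i||, free entries L[i, j], j < i
            diagMCC = (MC * C).sum(axis=1)  # sum_k (MC)_ik C_ik per row
            g_L = 2.0 * (MC - diagMCC[:, None] * C) / norms[:, None]
            g_corr = g_L[self.tril_rows, self.tril_cols]
        else:
            g_corr = np.zeros(0)

        return float(F), np.concatenate([g_lam, g_logtheta, g_corr])


def _start_cholesky(K: int, r0: float) -> np.ndarray:
    """Row-normalized-Cholesky start for an equicorrelation matrix."""
    Phi0 = np.full((K, K), r0)
    np.fill_diagonal(Phi0, 1.0)
    Cc = np.linalg.cholesky(Phi0)
    # rescale each row so its diagonal entry is 1 (the free parameterization)
    return Cc / np.diag(Cc)[:, None]


def fit_model(
    cov: pd.DataFrame,
    n_used: int,
    spec: ModelSpec,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one simple-structure model to a covariance matrix by ML.

    The returned solution is completely standardized: loadings are rescaled
    by the model-implied item standard deviations, so ``loading**2`` is the
    item variance explained by the factor.  ``loading_raw`` maps the estimate
    back to the original covariance scale.
    """
    options = options or FitOptions()
    cols = spec.columns
    missing = [c for c in cols if c not in cov.columns]
    if missing:
        raise KeyError(f"covariance matrix lacks columns {missing}")
    S = cov.loc[cols, cols].to_numpy(dtype=float)
    p = len(cols)
    d = np.sqrt(np.diag(S))
    if not np.all(d > 0):
        bad = [cols[i] for i in np.flatnonzero(~(d > 0))]
        raise DegenerateDataError(f"zero-variance column(s): {bad}")
    R = S / np.outer(d, d)
    R = 0.5 * (R + R.T)

    factor_names = spec.factor_names
    K = len(factor_names)
    fidx = np.array([factor_names.index(spec.factor_of(c)) for c in cols])

    prob = _MLProblem(R, fidx, K)
    lam0 = np.full(p, options.start_loading)
    theta0 = np.full(p, options.start_residual)
    L0 = _start_cholesky(K, options.start_correlation) if K > 1 else np.eye(1)
    x0 = prob.pack(lam0, theta0, L0) if options.x0 is None else np.asarray(options.x0, float)

    res = minimize(
        prob.value_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": options.max_iter,
            "gtol": options.gtol,
            "ftol": 1e-14,
            "maxcor": 30,
        },
    )
    lam, theta, L = prob.unpack(res.x)
    Phi, _, _ = prob.phi_of(L)

    # sign convention: flip factors whose mean loading is negative
    for k in range(K):
        sel = fidx == k
        if sel.any() and lam[sel].mean() < 0:
            lam[sel] = -lam[sel]
            Phi[k, :] *= -1.0
            Phi[:, k] *= -1.0
            Phi[k, k] = 1.0

    # completely standardized solution: rescale by model-implied item SDs
    implied_sd = np.sqrt(lam**2 + theta)
    lam_std = lam / implied_sd
    resid_std = theta / implied_sd**2
    lam_raw = lam * d / implied_sd  # loading in original item units

    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
    converged = bool(res.success or grad_norm < 1e-5)

    warn_msgs: list[str] = []
    near_heywood = np.flatnonzero(theta < options.heywood_tol)
    if near_heywood.size:
        msg = (
            "residual variance at the admissibility boundary (~0) for "
            f"item(s) {[cols[i] for i in near_heywood]}; the solution is a "
            "boundary (Heywood-type) solution"
        )
        warnings.warn(msg, HeywoodWarning, stacklevel=2)
        warn_msgs.append(msg)
    if K > 1:
        min_eig = float(np.linalg.eigvalsh(Phi).min())
        if min_eig < 1e-8:
            msg = (
                "the factor correlation matrix is singular "
                f"(smallest eigenvalue {min_eig:.2e}); factors may be "
                "empirically indistinguishable"
            )
            warnings.warn(msg, HeywoodWarning, stacklevel=2)
            warn_msgs.append(msg)

    loadings = pd.DataFrame(
        {
            "factor": [factor_names[i] for i in fidx],
            "loading": lam_std,
            "loading_raw": lam_raw,
            "residual_variance": resid_std,
        },
        index=pd.Index(cols, name="item"),
    )
    corr = pd.DataFrame(Phi, index=factor_names, columns=factor_names)
    return FitResult(
        model_level=spec.level,
        loadings=loadings,
        factor_correlations=corr,
        n_used=n_used,
        converged=converged,
        discrepancy_value=float(res.fun),
        iterations=int(res.nit),
        warnings=warn_msgs,
        internal_x=np.asarray(res.x, float),
    )


def fit_all(
    data: pd.DataFrame,
    naming: ItemNaming,
    options: FitOptions | None = None,
    missing: Literal["listwise", "pairwise"] = "listwise",
) -> list[FitResult]:
    """Fit the full nested model hierarchy to raw data.

    Prepares the covariance once, then fits every model derived from the
    naming, ordered general to specific.
    """
    cov, n_used = prepare_covariance(data[naming.columns], policy=missing)
    specs = specify_models(naming)
    return [fit_model(cov, n_used, spec, options) for spec in specs]


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

try:  # sklearn is optional at import time; the estimator needs it
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass


class ConfirmatoryFactorAnalysis(BaseEstimator):
    """Scikit-learn style estimator for one simple-structure CFA.

    Parameters
    ----------
    spec : ModelSpec
        Which factor each column measures.
    missing : {"listwise", "pairwise"}
        Missing-data policy for the covariance.
    max_iter, gtol : optimizer budget and gradient tolerance.

    Attributes
    ----------
    loadings_ : pandas.DataFrame
        Completely standardized loadings, one row per item.
    factor_correlations_ : pandas.DataFrame
        Latent correlation matrix.
    n_used_ : int
    converged_ : bool
    discrepancy_ : float
    n_iter_ : int
    result_ : FitResult
    """

    def __init__(
        self,
        spec: ModelSpec,
        missing: str = "listwise",
        max_iter: int = 10_000,
        gtol: float = 1e-8,
    ):
        self.spec = spec
        self.missing = missing
        self.max_iter = max_iter
        self.gtol = gtol

    def fit(self, X: pd.DataFrame, y=None) -> "ConfirmatoryFactorAnalysis":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.spec.columns)
        cov, n_used = prepare_covariance(X[self.spec.columns], policy=self.missing)
        return self.fit_covariance(cov, n_used)

    def fit_covariance(self, cov: pd.DataFrame, n_used: int) -> "ConfirmatoryFactorAnalysis":
        opts = FitOptions(max_iter=self.max_iter, gtol=self.gtol)
        result = fit_model(cov, n_used, self.spec, opts)
        self.result_ = result
        self.loadings_ = result.loadings
        self.factor_correlations_ = result.factor_correlations
        self.n_used_ = result.n_used
        self.converged_ = result.converged
        self.discrepancy_ = result.discrepancy_value
        self.n_iter_ = result.iterations
        return self
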