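"""Center distances: how much a specific factor outperforms a general one.

For an item i with completely standardized loading ``lambda_g`` on a general
factor and ``lambda_s`` on a more specific factor, the center distance is

    cd_i = lambda_s^2 / lambda_g^2 - 1   if |lambda_s| / |lambda_g| > 1
    cd_i = 0                             otherwise,

the relative gain in explained item variance from using the more specific
term.  A sub-pool k with m items is summarized either by the mean of its
item center distances or by the *aggregate* center distance

    cd_k = (sum_i lambda_is^2) / (sum_i lambda_ig^2) - 1,

the relative gain in explained variance across the whole sub-pool, which is
robust to items whose loadings are tiny in both models (their cd_i ratio can
be enormous while their contribution to explained variance is negligible).
The aggregate uses raw squared loadings on both sides, so it measures the
net gain and can be negative; negatives are truncated to zero only when
drawn.

The gate on |lambda_s|/|lambda_g| is evaluated on absolute loadings: an item
whose general loading is small and negative while its specific loading is
small and positive is exactly the kind of misfitting item the statistic
should expose, and a signed ratio would silently zero it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .cfa import FitResult
from .exceptions import StructuralError, UnboundedCenterDistanceWarning
from .naming import ItemNaming, facet_factor_name

__all__ = [
    "item_center_distance",
    "aggregate_center_distance",
    "mean_center_distance",
    "CenterDistanceTable",
    "XArrow",
    "EstimatesBundle",
    "build_estimates",
    "detect_xarrows",
]

#: |lambda_general| below this is treated as zero: the cd ratio is unbounded.
GENERAL_LOADING_EPS = 1e-6

#: Reported in place of an unbounded center distance (configurable per call).
DEFAULT_CD_CAP = 100.0


def item_center_distance(
    lambda_general: float,
    lambda_specific: float,
    cap: float = DEFAULT_CD_CAP,
) -> tuple[float, float]:
    """Per-item center distance ``(cd_raw, cd_display)``.

    ``cd_raw`` is the gated statistic (zero when the specific factor explains
    no more variance than the general one); ``cd_display`` additionally
    floors at zero, which under absolute-value gating changes nothing but is
    kept as the explicit display contract.

    A general loading within ``GENERAL_LOADING_EPS`` of zero makes the ratio
    unbounded; the value is capped at ``cap`` with a warning rather than
    returned infinite.
    """
    lg, ls = float(lambda_general), float(lambda_specific)
    if not (np.isfinite(lg) and np.isfinite(ls)):
        raise ValueError("loadings must be finite")
    if abs(lg) < GENERAL_LOADING_EPS:
        if abs(ls) <= abs(lg):
            return 0.0, 0.0
        warnings.warn(
            f"general loading {lg:.2e} is (near) zero; the center distance "
            f"is unbounded and was capped at {cap}",
            UnboundedCenterDistanceWarning,
            stacklevel=2,
        )
        return cap, cap
    if abs(ls) / abs(lg) > 1.0:
        cd = min(ls**2 / lg**2 - 1.0, cap)
    else:
        cd = 0.0
    return cd, max(cd, 0.0)


def aggregate_center_distance(
    pairs: Iterable[tuple[float, float]],
    cap: float = DEFAULT_CD_CAP,
) -> float:
    """Aggregate center distance of a sub-pool from (general, specific) loading pairs.

    Uses untruncated squared loadings on both sides, so the result is the net
    relative gain in explained variance and may be negative.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one loading pair")
    num = float((arr[:, 1] ** 2).sum())
    den = float((arr[:, 0] ** 2).sum())
    if den < GENERAL_LOADING_EPS**2 * len(arr):
        warnings.warn(
            "all general loadings are (near) zero; the aggregate center "
            f"distance is unbounded and was capped at {cap}",
            UnboundedCenterDistanceWarning,
            stacklevel=2,
        )
        return cap
    return min(num / den - 1.0, cap)


def mean_center_distance(
    pairs: Iterable[tuple[float, float]],
    cap: float = DEFAULT_CD_CAP,
    of_displayed: bool = False,
) -> float:
    """Mean of the per-item center distances of a sub-pool.

    ``of_displayed`` switches to averaging the display-floored values; with
    absolute-value gating the two coincide, but both variants are exposed.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one loading pair")
    idx = 1 if of_displayed else 0
    return float(
        np.mean([item_center_distance(lg, ls, cap=cap)[idx] for lg, ls in pairs])
    )


# ---------------------------------------------------------------------------
# tables and bundle
# ---------------------------------------------------------------------------

@dataclass
class CenterDistanceTable:
    """Item-wise and factor-wise center distances for one nested comparison."""

    items: pd.DataFrame
    """Index = item column name; columns: ``factor`` (the specific factor),
    ``lambda_general``, ``lambda_specific``, ``cd_raw``, ``cd_display``."""
    summaries: pd.DataFrame
    """Index = specific factor name; columns: ``mean_cd``, ``aggregate_cd``."""
    correlations: pd.DataFrame
    """Latent correlations among the specific factors."""
    comparison: tuple[str, str]
    """(general_level, specific_level)."""

    @property
    def factor_names(self) -> list[str]:
        return list(self.summaries.index)

    def cd_of(self, factor: str, cd_method: str = "aggregate") -> float:
        col = {"aggregate": "aggregate_cd", "mean": "mean_cd"}[cd_method]
        return float(self.summaries.loc[factor, col])

    def to_dict(self) -> dict:
        return {
            "comparison": list(self.comparison),
            "items": json.loads(self.items.to_json(orient="index")),
            "item_order": list(self.items.index),
            "summaries": json.loads(self.summaries.to_json(orient="index")),
            "factor_order": list(self.summaries.index),
            "correlations": {
                "factors": list(self.correlations.columns),
                "matrix": self.correlations.to_numpy().tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CenterDistanceTable":
        items = pd.DataFrame.from_dict(d["items"], orient="index").loc[d["item_order"]]
        items.index.name = "item"
        summaries = pd.DataFrame.from_dict(d["summaries"], orient="index").loc[
            d["factor_order"]
        ]
        summaries.index.name = "factor"
        names = d["correlations"]["factors"]
        corr = pd.DataFrame(
            np.asarray(d["correlations"]["matrix"], dtype=float),
            index=names,
            columns=names,
        )
        return cls(
            items=items,
            summaries=summaries,
            correlations=corr,
            comparison=tuple(d["comparison"]),
        )

    def to_csv(self, path) -> None:
        """Per-item cd table with the factor summaries repeated per row."""
        out = self.items.copy()
        out["mean_cd"] = [
            self.summaries.loc[f, "mean_cd"] for f in out["factor"]
        ]
        out["aggregate_cd"] = [
            self.summaries.loc[f, "aggregate_cd"] for f in out["factor"]
        ]
        out.to_csv(path, index_label="item")


@dataclass(frozen=True)
class XArrow:
    """A cross-test facet correlation exceeding its tests' correlation."""

    facet_a: str
    facet_b: str
    test_a: str
    test_b: str
    r_facets: float
    r_tests: float

    def to_dict(self) -> dict:
        return {
            "facet_a": self.facet_a,
            "facet_b": self.facet_b,
            "test_a": self.test_a,
            "test_b": self.test_b,
            "r_facets": self.r_facets,
            "r_tests": self.r_tests,
        }


@dataclass
class EstimatesBundle:
    """Everything chart creation needs, from one run of the model hierarchy.

    ``global_table`` compares the global model with the tests model (one row
    per item, one summary per test); ``test_tables`` compare the tests model
    with the facets model within each test.  ``raw`` keeps the full fit
    results, and ``xarrows`` lists cross-test facet pairs whose latent
    correlation exceeds that of their tests.
    """

    pool_name: str
    cd_method: str
    global_table: CenterDistanceTable
    test_tables: dict[str, CenterDistanceTable]
    cross_test_correlations: pd.DataFrame
    """Long format: facet_a, facet_b, test_a, test_b, r_facets, r_tests."""
    xarrows: list[XArrow]
    raw: list[FitResult]
    facet_test_map: dict[str, str] = field(default_factory=dict)

    @property
    def has_facets(self) -> bool:
        return bool(self.test_tables)

    @property
    def tests(self) -> list[str]:
        return list(self.global_table.summaries.index)

    def to_dict(self) -> dict:
        return {
            "pool_name": self.pool_name,
            "cd_method": self.cd_method,
            "global": self.global_table.to_dict(),
            "tests": {t: tab.to_dict() for t, tab in self.test_tables.items()},
            "cross_test_correlations": self.cross_test_correlations.to_dict(
                orient="records"
            ),
            "xarrows": [x.to_dict() for x in self.xarrows],
            "raw": [f.to_dict() for f in self.raw],
            "facet_test_map": dict(self.facet_test_map),
        }

    def to_json(self, path=None, indent: int = 1) -> str | None:
        text = json.dumps(self.to_dict(), indent=indent)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "EstimatesBundle":
        cross = pd.DataFrame(
            d["cross_test_correlations"],
            columns=["facet_a", "facet_b", "test_a", "test_b", "r_facets", "r_tests"],
        )
        return cls(
            pool_name=d["pool_name"],
            cd_method=d["cd_method"],
            global_table=CenterDistanceTable.from_dict(d["global"]),
            test_tables={
                t: CenterDistanceTable.from_dict(tab) for t, tab in d["tests"].items()
            },
            cross_test_correlations=cross,
            xarrows=[XArrow(**x) for x in d["xarrows"]],
            raw=[FitResult.from_dict(f) for f in d["raw"]],
            facet_test_map=dict(d.get("facet_test_map", {})),
        )

    @classmethod
    def from_json(cls, source) -> "EstimatesBundle":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                return cls.from_dict(json.load(fh))
        return cls.from_dict(json.loads(source))


def _cd_table(
    general: FitResult,
    specific: FitResult,
    item_columns: list[str],
    factor_order: list[str],
    corr: pd.DataFrame,
    cap: float,
) -> CenterDistanceTable:
    rows = []
    for col in item_columns:
        lg = general.loading_of(col)
        ls = specific.loading_of(col)
        cd_raw, cd_disp = item_center_distance(lg, ls, cap=cap)
        rows.append(
            {
                "factor": specific.loadings.loc[col, "factor"],
                "lambda_general": lg,
                "lambda_specific": ls,
                "cd_raw": cd_raw,
                "cd_display": cd_disp,
            }
        )
    items = pd.DataFrame(rows, index=pd.Index(item_columns, name="item"))
    summaries = pd.DataFrame(index=pd.Index(factor_order, name="factor"))
    means, aggs = [], []
    for fac in factor_order:
        sub = items[items["factor"] == fac]
        pairs = list(zip(sub["lambda_general"], sub["lambda_specific"]))
        means.append(mean_center_distance(pairs, cap=cap))
        aggs.append(aggregate_center_distance(pairs, cap=cap))
    summaries["mean_cd"] = means
    summaries["aggregate_cd"] = aggs
    return CenterDistanceTable(
        items=items,
        summaries=summaries,
        correlations=corr.loc[factor_order, factor_order],
        comparison=(general.model_level, specific.model_level),
    )


def build_estimates(
    fits: list[FitResult],
    naming: ItemNaming,
    cd_method: Literal["aggregate", "mean"] = "aggregate",
    cap: float = DEFAULT_CD_CAP,
    allow_unconverged: bool = False,
) -> EstimatesBundle:
    """Assemble the full estimates bundle from the fitted model hierarchy.

    ``fits`` must be ordered general to specific ([global, tests] or
    [global, tests, facets]) with identical item sets.
    """
    if len(fits) not in (2, 3):
        raise StructuralError("need two or three fits, ordered general to specific")
    if cd_method not in ("aggregate", "mean"):
        raise ValueError(f"unknown cd_method {cd_method!r}")
    item_sets = [set(f.loadings.index) for f in fits]
    if any(s != item_sets[0] for s in item_sets[1:]):
        raise StructuralError("fits cover different item sets")
    if set(naming.columns) != item_sets[0]:
        raise StructuralError("fits do not cover the naming's item columns")
    for f in fits:
        f.require_converged(allow_unconverged)

    global_fit, tests_fit = fits[0], fits[1]
    cols = naming.columns
    tests = naming.tests
    global_table = _cd_table(
        global_fit, tests_fit, cols, tests, tests_fit.factor_correlations, cap
    )

    test_tables: dict[str, CenterDistanceTable] = {}
    cross = pd.DataFrame(
        columns=["facet_a", "facet_b", "test_a", "test_b", "r_facets", "r_tests"]
    )
    facet_test_map: dict[str, str] = {}
    if len(fits) == 3:
        facets_fit = fits[2]
        for test, facet in naming.facet_pairs:
            facet_test_map[facet_factor_name(naming, test, facet)] = test
        for test in tests:
            fac_names = [
                facet_factor_name(naming, test, fac) for fac in naming.facets_of(test)
            ]
            test_cols = [it.column for it in naming.items_of_test(test)]
            test_tables[test] = _cd_table(
                tests_fit,
                facets_fit,
                test_cols,
                fac_names,
                facets_fit.factor_correlations,
                cap,
            )
        records = []
        all_facets = list(facet_test_map)
        for i, fa in enumerate(all_facets):
            for fb in all_facets[i + 1 :]:
                ta, tb = facet_test_map[fa], facet_test_map[fb]
                if ta == tb:
                    continue
                records.append(
                    {
                        "facet_a": fa,
                        "facet_b": fb,
                        "test_a": ta,
                        "test_b": tb,
                        "r_facets": facets_fit.correlation(fa, fb),
                        "r_tests": tests_fit.correlation(ta, tb),
                    }
                )
        if records:
            cross = pd.DataFrame(records)

    bundle = EstimatesBundle(
        pool_name=naming.pool_name,
        cd_method=cd_method,
        global_table=global_table,
        test_tables=test_tables,
        cross_test_correlations=cross,
        xarrows=[],
        raw=fits,
        facet_test_map=facet_test_map,
    )
    bundle.xarrows = detect_xarrows(bundle)
    return bundle


def detect_xarrows(bundle: EstimatesBundle) -> list[XArrow]:
    """Cross-test facet pairs whose correlation exceeds their tests' correlation.

    Strict inequality; sorted descending by the facet correlation.  These are
    the pairs worth drawing as dotted arrows in a nested chart: each marks a
    commonality between facets beyond the similarity of their parent pools.
    """
    out: list[XArrow] = []
    for rec in bundle.cross_test_correlations.itertuples(index=False):
        if rec.r_facets > rec.r_tests:
            out.append(
                XArrow(
                    facet_a=rec.facet_a,
                    facet_b=rec.facet_b,
                    test_a=rec.test_a,
                    test_b=rec.test_b,
                    r_facets=float(rec.r_facets),
                    r_tests=float(rec.r_tests),
                )
            )
    return sorted(out, key=lambda x: -x.r_facets)
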