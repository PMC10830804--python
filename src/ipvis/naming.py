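"""Item naming convention and automatic model specification.

Item pools are described entirely by their column names.  A three-part name
``test_facet_item`` (e.g. ``H_Mode_Mode9``) places an item in a facet nested
in a test; a two-part name ``test_item`` gives a flat test/item hierarchy.
From a parsed :class:`ItemNaming`, :func:`specify_models` derives the nested
hierarchy of confirmatory factor models that the package compares:

* a *global* model — one factor across the whole pool,
* a *tests* model — one factor per test, all pairs correlated,
* a *facets* model (three-part names only) — one factor per facet, all pairs
  correlated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .exceptions import (
    DuplicateItemError,
    NamingFormatError,
    UnderIdentifiedFactorWarning,
)

__all__ = ["Item", "ItemNaming", "ModelSpec", "parse_columns", "specify_models"]


@dataclass(frozen=True)
class Item:
    """One item column, resolved against the naming convention."""

    test: str
    facet: str | None
    item: str
    column: str
    index: int

    @property
    def triple(self) -> tuple[str, str | None, str]:
        return (self.test, self.facet, self.item)


@dataclass
class ItemNaming:
    """The parsed test/facet/item hierarchy of an item pool.

    Parameters
    ----------
    items : list of Item
        In original column order.
    pool_name : str
        User-supplied name of the total item pool (the global factor).
    separator : str
        The separator the names were split on.
    """

    items: list[Item]
    pool_name: str
    separator: str = "_"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str | None, str]] = set()
        for it in self.items:
            if it.triple in seen:
                raise DuplicateItemError(
                    f"duplicate item name {it.column!r}: the "
                    f"(test, facet, item) triple {it.triple} occurs twice"
                )
            seen.add(it.triple)
        facet_flags = {it.facet is not None for it in self.items}
        if len(facet_flags) > 1:
            raise NamingFormatError(
                "mixed two-part and three-part names in one pool"
            )

    @property
    def has_facets(self) -> bool:
        return bool(self.items) and self.items[0].facet is not None

    @property
    def columns(self) -> list[str]:
        return [it.column for it in self.items]

    @property
    def tests(self) -> list[str]:
        """Test labels in order of first appearance."""
        out: list[str] = []
        for it in self.items:
            if it.test not in out:
                out.append(it.test)
        return out

    def facets_of(self, test: str) -> list[str]:
        """Facet labels of one test, in order of first appearance."""
        out: list[str] = []
        for it in self.items:
            if it.test == test and it.facet is not None and it.facet not in out:
                out.append(it.facet)
        return out

    @property
    def facet_pairs(self) -> list[tuple[str, str]]:
        """(test, facet) pairs in order of first appearance."""
        out: list[tuple[str, str]] = []
        for it in self.items:
            if it.facet is not None and (it.test, it.facet) not in out:
                out.append((it.test, it.facet))
        return out

    def items_of_test(self, test: str) -> list[Item]:
        return [it for it in self.items if it.test == test]

    def items_of_facet(self, test: str, facet: str) -> list[Item]:
        return [it for it in self.items if it.test == test and it.facet == facet]

    @property
    def duplicate_facet_labels(self) -> list[str]:
        """Facet labels reused across tests (facet identity is the (test, facet) pair)."""
        by_label: dict[str, set[str]] = {}
        for test, facet in self.facet_pairs:
            by_label.setdefault(facet, set()).add(test)
        return [lab for lab, tests in by_label.items() if len(tests) > 1]


@dataclass
class ModelSpec:
    """One confirmatory factor model: which factor each item measures.

    All factor pairs are correlated (fully correlated simple-structure model);
    ``correlated_pairs`` enumerates them.
    """

    level: str  # "global" | "tests" | "facets"
    factors: dict[str, list[str]]  # factor name -> column names, in data order
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in ("global", "tests", "facets"):
            raise ValueError(f"unknown model level {self.level!r}")
        if self.level == "global" and len(self.factors) != 1:
            raise ValueError("a global model has exactly one factor")
        seen: set[str] = set()
        for name, cols in self.factors.items():
            if not cols:
                raise ValueError(f"factor {name!r} has no items")
            overlap = seen.intersection(cols)
            if overlap:
                raise ValueError(f"items in more than one factor: {sorted(overlap)}")
            seen.update(cols)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors)

    @property
    def columns(self) -> list[str]:
        out: list[str] = []
        for cols in self.factors.values():
            out.extend(cols)
        return out

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def correlated_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.factors, 2))

    def factor_of(self, column: str) -> str:
        for name, cols in self.factors.items():
            if column in cols:
                return name
        raise KeyError(column)

    def to_dict(self) -> dict:
        return {"level": self.level, "factors": {k: list(v) for k, v in self.factors.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(level=d["level"], factors={k: list(v) for k, v in d["factors"].items()})


def parse_columns(
    column_names: list[str], pool_name: str, separator: str = "_"
) -> ItemNaming:
    """Parse column names into the test/facet/item hierarchy.

    Every name must split on ``separator`` into exactly two
    (``test_item``) or exactly three (``test_facet_item``) non-empty parts,
    consistently across all columns.  Any other column is treated as a
    non-item variable and rejected: the data may not contain additional
    variables because every column enters the factor models.
    """
    if not column_names:
        raise NamingFormatError("no columns given")
    if not separator:
        raise ValueError("separator must be a non-empty string")

    n_parts: int | None = None
    items: list[Item] = []
    for idx, name in enumerate(column_names):
        parts = name.split(separator)
        if len(parts) not in (2, 3) or any(p == "" for p in parts):
            raise NamingFormatError(
                f"column {name!r} does not follow the "
                f"'test{separator}facet{separator}item' or "
                f"'test{separator}item' convention"
            )
        if n_parts is None:
            n_parts = len(parts)
        elif len(parts) != n_parts:
            raise NamingFormatError(
                f"column {name!r} has {len(parts)} name parts but earlier "
                f"columns have {n_parts}; two-part and three-part names "
                "cannot be mixed"
            )
        if n_parts == 2:
            test, item = parts
            facet: str | None = None
        else:
            test, facet, item = parts
        items.append(Item(test=test, facet=facet, item=item, column=name, index=idx))

    return ItemNaming(items=items, pool_name=pool_name, separator=separator)


def _check_factor_sizes(factors: dict[str, list[str]], level: str) -> list[str]:
    notes = []
    for name, cols in factors.items():
        if len(cols) == 1:
            raise NamingFormatError(
                f"factor {name!r} in the {level} model has a single item; "
                "one-item factors are not identifiable in this model family"
            )
        if len(cols) < 3:
            msg = (
                f"factor {name!r} in the {level} model has only {len(cols)} "
                "items; it is identified only through its correlations with "
                "other factors"
            )
            warnings.warn(msg, UnderIdentifiedFactorWarning, stacklevel=3)
            notes.append(msg)
    return notes


def specify_models(naming: ItemNaming) -> list[ModelSpec]:
    """Derive the nested model hierarchy from an item naming.

    Returns ``[global, tests]`` for two-part names and
    ``[global, tests, facets]`` for three-part names, ordered general to
    specific.  Factors appear in order of first appearance in the data; each
    model's factor item sets partition the pool.
    """
    cols = naming.columns
    specs = [ModelSpec(level="global", factors={naming.pool_name: list(cols)})]

    test_factors: dict[str, list[str]] = {}
    for it in naming.items:
        test_factors.setdefault(it.test, []).append(it.column)
    notes = [] if len(test_factors) == 1 else _check_factor_sizes(test_factors, "tests")
    specs.append(ModelSpec(level="tests", factors=test_factors, notes=notes))

    if naming.has_facets:
        dup = set(naming.duplicate_facet_labels)
        facet_factors: dict[str, list[str]] = {}
        facet_notes: list[str] = []
        for test, facet in naming.facet_pairs:
            # facet identity is the (test, facet) pair; a reused label is
            # disambiguated by prefixing the test
            name = f"{test}{naming.separator}{facet}" if facet in dup else facet
            facet_factors[name] = [it.column for it in naming.items_of_facet(test, facet)]
        if dup:
            facet_notes.append(
                "facet labels reused across tests were disambiguated with a "
                f"test prefix: {sorted(dup)}"
            )
        facet_notes += _check_factor_sizes(facet_factors, "facets")
        specs.append(ModelSpec(level="facets", factors=facet_factors, notes=facet_notes))

    return specs


def facet_factor_name(naming: ItemNaming, test: str, facet: str) -> str:
    """The factor name used for a (test, facet) pair in the facets model."""
    if facet in naming.duplicate_facet_labels:
        return f"{test}{naming.separator}{facet}"
    return facet
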