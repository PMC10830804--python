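"""Radial chart family: item charts, facet charts, nested charts, item overview.

Every chart is first laid out as a :class:`SceneGraph` — an ordered list of
geometric primitives (circle, ray, bar, arrow, text) in *chart units*, where
one unit of radial distance equals one unit of center distance (times the
layer's axis scale).  Each primitive that encodes a center distance carries
the encoded value and its axis scale in its tags, so chart geometry is fully
testable without rasterization.  :func:`render` draws a scene to PDF/SVG
(vector) or PNG/JPEG (raster) with matplotlib.

Layout conventions
------------------
* Facet circles are evenly spaced starting at 12 o'clock, clockwise, in
  factor order; per-factor rotation offsets (degrees, clockwise) come from
  the config.
* A facet's circle has radius ``subradius`` and its *nearest edge* sits at
  radial distance cd from the center; a black bar runs from the center to
  that edge.  The dotted central circle marks the axis scale: its radius is
  the largest of 1, 2 or 5 times a power of ten not exceeding half the
  maximum displayed cd.
* Negative aggregate center distances are drawn at 0 and flagged
  (``truncated`` tag) — truncation happens only here, at the chart layer.
* Nested charts lay out the global layer first; each test circle's radius is
  fixed by the data (the test's inner chart extent divided by the automatic
  relative scaling), so changing ``relative_scaling`` rescales only the
  nested layers.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .center_distance import CenterDistanceTable, EstimatesBundle, XArrow
from .exceptions import ChartConfigError, ChartLayoutWarning, RelativeScalingWarning

__all__ = [
    "ChartConfig",
    "Primitive",
    "SceneGraph",
    "choose_axis_tick",
    "layout_facet_chart",
    "layout_item_chart",
    "layout_nested_chart",
    "layout_item_overview",
    "render",
    "facet_chart",
    "item_chart",
    "nested_chart",
    "item_overview",
]

#: layer palette: global gray, test layer light blue, facet layer darker blue
DEFAULT_COLORS = {
    "global": "#b0b0b0",
    "tests": "#89b8d4",
    "facets": "#2a6b9c",
    "bar": "#000000",
    "text": "#000000",
    "arrow": "#555555",
}


@dataclass
class ChartConfig:
    """Appearance parameters for one chart rendering."""

    chart_type: Literal["item", "facet", "nested", "overview"] = "facet"
    cd_method: Literal["aggregate", "mean"] | None = None  # None: bundle default
    subradius: float | None = None  # facet-circle radius, chart units; None: auto
    relative_scaling: float | None = None  # nested only; None: auto
    rotations: dict[str, float] = field(default_factory=dict)  # factor -> degrees cw
    zoom_x: tuple[float, float] | None = None
    zoom_y: tuple[float, float] | None = None
    size: float = 1.0  # global multiplier for widths and font sizes
    width_circles: float = 1.0
    width_bars: float = 1.0
    width_arrows: float = 1.0
    size_text: float = 1.0
    size_values: float = 1.0
    relabel: dict[str, str] = field(default_factory=dict)
    colors: dict[str, str] = field(default_factory=dict)
    file_name: str | None = None
    dpi: int = 300
    show_xarrows: bool = True
    xarrows: list[tuple[str, str]] | None = None  # override selection
    axis_tick: float | None = None  # override the dotted-circle value

    def __post_init__(self) -> None:
        if self.subradius is not None and not self.subradius > 0:
            raise ChartConfigError("subradius must be positive")
        if self.relative_scaling is not None and not self.relative_scaling > 0:
            raise ChartConfigError("relative_scaling must be positive")
        for name in ("zoom_x", "zoom_y"):
            win = getattr(self, name)
            if win is not None:
                lo, hi = win
                if not lo < hi:
                    raise ChartConfigError(
                        f"{name} must be a proper nonempty interval, got {win}"
                    )
        if self.dpi <= 0:
            raise ChartConfigError("dpi must be positive")
        if self.size <= 0:
            raise ChartConfigError("size must be positive")

    def color(self, key: str) -> str:
        return self.colors.get(key, DEFAULT_COLORS[key])

    def label(self, name: str) -> str:
        return self.relabel.get(name, name)


@dataclass
class Primitive:
    """One geometric element with semantic tags.

    ``coords`` are chart units: circles have ``x, y, r``; rays and arrows
    ``x1, y1, x2, y2``; bars (axis-aligned rectangles) ``x, y, w, h``; text
    ``x, y``.  Tags record what the element encodes — notably ``value`` (a
    cd or correlation), ``axis_scale`` and ``radial`` (the radial coordinate
    of the encoding, relative to the layer center) for cd-encoding elements.
    """

    kind: Literal["circle", "arc", "ray", "bar", "arrow", "text"]
    coords: dict
    style: dict = field(default_factory=dict)
    tags: dict = field(default_factory=dict)
    text: str | None = None

    def transformed(self, scale: float, dx: float, dy: float) -> "Primitive":
        c = dict(self.coords)
        for kx, ky in (("x", "y"), ("x1", "y1"), ("x2", "y2")):
            if kx in c:
                c[kx] = c[kx] * scale + dx
                c[ky] = c[ky] * scale + dy
        for k in ("r", "w", "h"):
            if k in c:
                c[k] = c[k] * scale
        tags = dict(self.tags)
        if "axis_scale" in tags:
            tags["axis_scale"] = tags["axis_scale"] * scale
        if "radial" in tags:
            tags["radial"] = tags["radial"] * scale
        return Primitive(kind=self.kind, coords=c, style=dict(self.style), tags=tags, text=self.text)


@dataclass
class SceneGraph:
    """Ordered primitives plus the chart extent (xmin, xmax, ymin, ymax)."""

    primitives: list[Primitive] = field(default_factory=list)
    extent: tuple[float, float, float, float] = (-1.0, 1.0, -1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def add(self, prim: Primitive) -> None:
        self.primitives.append(prim)

    def filter(self, kind: str | None = None, role: str | None = None) -> list[Primitive]:
        out = self.primitives
        if kind is not None:
            out = [p for p in out if p.kind == kind]
        if role is not None:
            out = [p for p in out if p.tags.get("role") == role]
        return out

    def to_json(self, path=None, indent: int = 1) -> str | None:
        payload = {
            "extent": list(self.extent),
            "meta": self.meta,
            "primitives": [asdict(p) for p in self.primitives],
        }
        text = json.dumps(payload, indent=indent)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def choose_axis_tick(max_cd: float) -> float:
    """Dotted-circle value: largest 1/2/5 x 10^k not exceeding max_cd / 2."""
    if not max_cd > 0:
        return 0.1
    target = max_cd / 2.0
    best = 0.001
    for k in range(-3, 4):
        for m in (1.0, 2.0, 5.0):
            v = m * 10.0**k
            if v <= target and v > best:
                best = v
    return best


def _angle(j: int, n: int, rotation_deg: float = 0.0) -> float:
    """Angle (radians) of slot j of n: 12 o'clock start, clockwise."""
    return math.pi / 2.0 - 2.0 * math.pi * j / n - math.radians(rotation_deg)


def _fmt_r(r: float) -> str:
    s = f"{r:.2f}"
    return s.replace("0.", ".", 1) if abs(r) < 1.0 else s


def _displayed_cds(table: CenterDistanceTable, cd_method: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    names = table.factor_names
    raw = np.array([table.cd_of(f, cd_method) for f in names], dtype=float)
    return names, raw, np.maximum(raw, 0.0)


def _place_value_texts(
    scene: SceneGraph,
    entries: list[tuple[float, tuple[float, float], tuple[float, float], dict]],
    min_dist: float,
    style: dict,
) -> None:
    """Greedy overlap-free placement of correlation values.

    ``entries``: (value, midpoint, unit-perpendicular, tags), processed in
    descending |value|; each text starts at the chord midpoint and is nudged
    outward along the perpendicular (alternating sides) until it clears the
    already placed texts.
    """
    placed: list[tuple[float, float]] = []
    for value, (mx, my), (px, py), tags in sorted(
        entries, key=lambda e: -abs(e[0])
    ):
        pos = (mx, my)
        for step in range(0, 40):
            k = (step + 1) // 2 * (1 if step % 2 else -1)
            cand = (mx + px * k * min_dist, my + py * k * min_dist)
            if all(math.dist(cand, q) >= min_dist for q in placed):
                pos = cand
                break
        placed.append(pos)
        scene.add(
            Primitive(
                kind="text",
                coords={"x": pos[0], "y": pos[1]},
                style=style,
                tags=tags,
                text=_fmt_r(value),
            )
        )


def layout_facet_chart(
    table: CenterDistanceTable,
    config: ChartConfig | None = None,
    correlations: "np.ndarray | None" = None,
    title: str | None = None,
    layer: str = "tests",
    circle_color_key: str = "facets",
) -> SceneGraph:
    """Radial chart of one sub-pool's aggregate (or mean) center distances.

    One circle per factor, nearest edge at its cd; black bars encode the
    cds; correlations printed along the factor-pair chords.
    """
    config = config or ChartConfig(chart_type="facet")
    cd_method = config.cd_method or "aggregate"
    names, raw_cds, cds = _displayed_cds(table, cd_method)
    n = len(names)
    max_cd = float(cds.max()) if n else 0.0

    tick = config.axis_tick or choose_axis_tick(max_cd)
    sub = config.subradius
    if sub is None:
        sub = max(0.15 * max_cd, 0.25 * tick)
    R_out = max_cd + 2.0 * sub

    scene = SceneGraph(meta={"chart_type": "facet", "cd_method": cd_method, "tick": tick, "subradius": sub})
    lw_c = 1.2 * config.width_circles * config.size
    scene.add(
        Primitive(
            "circle",
            {"x": 0.0, "y": 0.0, "r": R_out},
            {"color": config.color(layer), "lw": 1.8 * config.width_circles * config.size},
            {"role": "pool_circle", "layer": layer},
        )
    )
    scene.add(
        Primitive(
            "circle",
            {"x": 0.0, "y": 0.0, "r": tick},
            {"color": config.color("text"), "lw": 0.8 * config.size, "ls": ":"},
            {"role": "axis_tick", "value": tick, "axis_scale": 1.0, "radial": tick},
        )
    )
    if title is not None:
        scene.add(
            Primitive(
                "text",
                {"x": 0.0, "y": R_out - 0.6 * sub},
                {"fontsize": 12.0 * config.size_text * config.size, "color": config.color("text")},
                {"role": "pool_label", "factor": title},
                text=config.label(title),
            )
        )

    centers: dict[str, tuple[float, float]] = {}
    for j, (name, cd_raw, cd) in enumerate(zip(names, raw_cds, cds)):
        th = _angle(j, n, config.rotations.get(name, 0.0))
        cx, cy = (cd + sub) * math.cos(th), (cd + sub) * math.sin(th)
        centers[name] = (cx, cy)
        scene.add(
            Primitive(
                "ray",
                {"x1": 0.0, "y1": 0.0, "x2": cd * math.cos(th), "y2": cd * math.sin(th)},
                {"color": config.color("bar"), "lw": 2.5 * config.width_bars * config.size},
                {
                    "role": "cd_bar",
                    "factor": name,
                    "value": cd,
                    "axis_scale": 1.0,
                    "radial": cd,
                    "truncated": bool(cd_raw < 0),
                },
            )
        )
        scene.add(
            Primitive(
                "circle",
                {"x": cx, "y": cy, "r": sub},
                {"color": config.color(circle_color_key), "lw": lw_c},
                {
                    "role": "facet_circle",
                    "factor": name,
                    "value": cd,
                    "axis_scale": 1.0,
                    "radial": cd,
                    "truncated": bool(cd_raw < 0),
                },
            )
        )
        scene.add(
            Primitive(
                "text",
                {"x": cx, "y": cy},
                {"fontsize": 10.0 * config.size_text * config.size, "color": config.color("text")},
                {"role": "facet_label", "factor": name},
                text=config.label(name),
            )
        )

    if correlations is None:
        correlations = table.correlations.to_numpy()
    if n >= 2:
        entries = []
        for i in range(n):
            for j in range(i + 1, n):
                a, b = centers[names[i]], centers[names[j]]
                mx, my = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
                dxv, dyv = b[0] - a[0], b[1] - a[1]
                norm = math.hypot(dxv, dyv) or 1.0
                perp = (-dyv / norm, dxv / norm)
                entries.append(
                    (
                        float(correlations[i, j]),
                        (mx, my),
                        perp,
                        {"role": "correlation", "factors": (names[i], names[j]),
                         "value": float(correlations[i, j])},
                    )
                )
        _place_value_texts(
            scene,
            entries,
            min_dist=max(0.35 * tick, 0.3 * sub),
            style={"fontsize": 9.0 * config.size_values * config.size, "color": config.color("text")},
        )

    # overlap diagnostics
    pts = list(centers.values())
    if len(pts) >= 2:
        dmin = min(
            math.dist(pts[i], pts[j])
            for i in range(len(pts))
            for j in range(i + 1, len(pts))
        )
        if dmin < 2.0 * sub - 1e-9:
            warnings.warn(
                f"facet circles overlap at subradius {sub:.3g}; "
                f"try subradius <= {dmin / 2.0:.3g}",
                ChartLayoutWarning,
                stacklevel=2,
            )

    scene.extent = (-R_out * 1.05, R_out * 1.05, -R_out * 1.05, R_out * 1.05)
    return scene


def layout_item_chart(
    table: CenterDistanceTable,
    config: ChartConfig | None = None,
    title: str | None = None,
) -> SceneGraph:
    """Radial chart of per-item center distances, grouped in facet sectors."""
    config = config or ChartConfig(chart_type="item")
    items = table.items
    names = table.factor_names
    n = len(names)
    cds = items["cd_display"].to_numpy(dtype=float)
    max_cd = float(cds.max()) if len(cds) else 0.0
    tick = config.axis_tick or choose_axis_tick(max_cd)
    R_out = max(1.1 * max_cd, 1.5 * tick)  # extent grows to fit outliers

    scene = SceneGraph(
        meta={"chart_type": "item", "tick": tick, "n_factors": n}
    )
    r = tick
    while r <= R_out + 1e-12:
        scene.add(
            Primitive(
                "circle",
                {"x": 0.0, "y": 0.0, "r": r},
                {"color": config.color("text"), "lw": 0.8 * config.size, "ls": ":"},
                {"role": "axis_tick", "value": r, "axis_scale": 1.0, "radial": r},
            )
        )
        r += tick
    if title is not None:
        scene.add(
            Primitive(
                "text",
                {"x": 0.0, "y": R_out * 1.12},
                {"fontsize": 12.0 * config.size_text * config.size, "color": config.color("text")},
                {"role": "pool_label", "factor": title},
                text=config.label(title),
            )
        )

    sector = 2.0 * math.pi / n if n else 2.0 * math.pi
    for j, name in enumerate(names):
        th0 = _angle(j, n, config.rotations.get(name, 0.0))
        # sector boundaries
        for edge in (-0.5, 0.5):
            th = th0 - edge * sector
            scene.add(
                Primitive(
                    "ray",
                    {"x1": 0.0, "y1": 0.0, "x2": R_out * math.cos(th), "y2": R_out * math.sin(th)},
                    {"color": config.color("global"), "lw": 0.6 * config.size, "alpha": 0.6},
                    {"role": "sector_boundary", "factor": name},
                )
            )
        scene.add(
            Primitive(
                "text",
                {"x": R_out * 1.08 * math.cos(th0), "y": R_out * 1.08 * math.sin(th0)},
                {"fontsize": 11.0 * config.size_text * config.size, "color": config.color("text")},
                {"role": "facet_label", "factor": name},
                text=config.label(name),
            )
        )
        sub = items[items["factor"] == name]
        m = len(sub)
        for k, (item, row) in enumerate(sub.iterrows()):
            frac = (k + 1) / (m + 1) - 0.5  # within-sector position
            th = th0 - 0.86 * frac * sector
            cd = float(row["cd_display"])
            tip = (cd * math.cos(th), cd * math.sin(th))
            scene.add(
                Primitive(
                    "ray",
                    {"x1": 0.0, "y1": 0.0, "x2": tip[0], "y2": tip[1]},
                    {"color": config.color("facets"), "lw": 1.2 * config.width_bars * config.size},
                    {"role": "item_ray", "item": item, "factor": name,
                     "value": cd, "axis_scale": 1.0, "radial": cd},
                )
            )
            scene.add(
                Primitive(
                    "circle",
                    {"x": tip[0], "y": tip[1], "r": 0.012 * R_out},
                    {"color": config.color("facets"), "lw": 0.0, "fill": True},
                    {"role": "item_marker", "item": item, "factor": name,
                     "value": cd, "axis_scale": 1.0, "radial": cd},
                )
            )
            lab = (cd + 0.05 * R_out)
            scene.add(
                Primitive(
                    "text",
                    {"x": lab * math.cos(th), "y": lab * math.sin(th)},
                    {"fontsize": 6.5 * config.size_text * config.size, "color": config.color("text")},
                    {"role": "item_label", "item": item, "factor": name},
                    text=config.label(item.split("_")[-1] if isinstance(item, str) else str(item)),
                )
            )

    ext = R_out * 1.2
    scene.extent = (-ext, ext, -ext, ext)
    return scene


def _auto_relative_scaling(inner_extents: dict[str, float], reference: float) -> float:
    """Smallest scaling >= 1 keeping every inner chart within its host radius
    budget (largest inner extent drawn no larger than the reference length)."""
    if not inner_extents or reference <= 0:
        return 1.0
    return max(1.0, max(inner_extents.values()) / reference)


def layout_nested_chart(
    bundle: EstimatesBundle,
    config: ChartConfig | None = None,
) -> SceneGraph:
    """Facet chart of the whole pool with each test circle containing that
    test's own facet chart.

    The test circle radii are part of the global layer and are fixed by the
    data: inner extent divided by the *automatic* relative scaling.  An
    explicit ``relative_scaling`` rescales only the nested layers; values
    below the automatic one make the inner charts overflow their hosts
    (warned, with the fitting value suggested).
    """
    config = config or ChartConfig(chart_type="nested")
    if not bundle.has_facets:
        raise ChartConfigError(
            "nested charts need a facet-level subdivision; this bundle has "
            "only the global comparison"
        )
    cd_method = config.cd_method or bundle.cd_method

    # inner facet charts, one per test, in their own cd units
    inner_cfg = ChartConfig(
        chart_type="facet",
        cd_method=cd_method,
        subradius=config.subradius,
        rotations=config.rotations,
        size=config.size,
        width_circles=config.width_circles,
        width_bars=config.width_bars,
        size_text=config.size_text,
        size_values=config.size_values,
        relabel=config.relabel,
        colors=config.colors,
        axis_tick=config.axis_tick,
    )
    inner: dict[str, SceneGraph] = {}
    inner_extent: dict[str, float] = {}
    for test, table in bundle.test_tables.items():
        sc = layout_facet_chart(table, inner_cfg, layer="tests", circle_color_key="facets")
        inner[test] = sc
        # the enclosing circle of the inner chart
        inner_extent[test] = sc.filter(kind="circle", role="pool_circle")[0].coords["r"]

    gtab = bundle.global_table
    tests, raw_gcds, gcds = _displayed_cds(gtab, cd_method)
    max_gcd = float(gcds.max())
    gtick = choose_axis_tick(max_gcd)
    reference = max(max_gcd, gtick)
    rs_auto = _auto_relative_scaling(inner_extent, reference)
    rs = config.relative_scaling if config.relative_scaling is not None else rs_auto
    if rs != 1.0:
        warnings.warn(
            f"relative_scaling is {rs:.3g} (not 1): the nested axis scale "
            "differs from the global one; readers should be told",
            RelativeScalingWarning,
            stacklevel=2,
        )

    host_radius = {t: inner_extent[t] / rs_auto for t in inner}
    overflow = {t for t in inner if inner_extent[t] / rs > host_radius[t] * (1 + 1e-9)}
    if overflow:
        warnings.warn(
            f"nested chart(s) {sorted(overflow)} exceed their host circles at "
            f"relative_scaling {rs:.3g}; try relative_scaling >= {rs_auto:.3g}",
            ChartLayoutWarning,
            stacklevel=2,
        )

    scene = SceneGraph(
        meta={
            "chart_type": "nested",
            "cd_method": cd_method,
            "tick": gtick,
            "relative_scaling": rs,
            "relative_scaling_auto": rs_auto,
        }
    )
    R_out = max(gcds[j] + 2.0 * host_radius[t] for j, t in enumerate(tests))
    scene.add(
        Primitive(
            "circle",
            {"x": 0.0, "y": 0.0, "r": R_out},
            {"color": config.color("global"), "lw": 2.0 * config.width_circles * config.size},
            {"role": "pool_circle", "layer": "global"},
        )
    )
    scene.add(
        Primitive(
            "circle",
            {"x": 0.0, "y": 0.0, "r": gtick},
            {"color": config.color("text"), "lw": 0.8 * config.size, "ls": ":"},
            {"role": "axis_tick", "value": gtick, "axis_scale": 1.0, "radial": gtick,
             "layer": "global"},
        )
    )
    scene.add(
        Primitive(
            "text",
            {"x": 0.0, "y": R_out * 1.04},
            {"fontsize": 13.0 * config.size_text * config.size, "color": config.color("text")},
            {"role": "pool_label", "factor": bundle.pool_name, "layer": "global"},
            text=config.label(bundle.pool_name),
        )
    )

    n = len(tests)
    test_center: dict[str, tuple[float, float]] = {}
    for j, (test, cd_raw, cd) in enumerate(zip(tests, raw_gcds, gcds)):
        th = _angle(j, n, config.rotations.get(test, 0.0))
        rho = host_radius[test]
        cx, cy = (cd + rho) * math.cos(th), (cd + rho) * math.sin(th)
        test_center[test] = (cx, cy)
        scene.add(
            Primitive(
                "ray",
                {"x1": 0.0, "y1": 0.0, "x2": cd * math.cos(th), "y2": cd * math.sin(th)},
                {"color": config.color("bar"), "lw": 3.0 * config.width_bars * config.size},
                {"role": "cd_bar", "factor": test, "value": cd, "axis_scale": 1.0,
                 "radial": cd, "layer": "global", "truncated": bool(cd_raw < 0)},
            )
        )
        scene.add(
            Primitive(
                "circle",
                {"x": cx, "y": cy, "r": rho},
                {"color": config.color("tests"), "lw": 1.6 * config.width_circles * config.size},
                {"role": "facet_circle", "factor": test, "value": cd, "axis_scale": 1.0,
                 "radial": cd, "layer": "global", "truncated": bool(cd_raw < 0)},
            )
        )
        scene.add(
            Primitive(
                "text",
                {"x": cx, "y": cy + rho * 1.12},
                {"fontsize": 11.0 * config.size_text * config.size, "color": config.color("text")},
                {"role": "facet_label", "factor": test, "layer": "global"},
                text=config.label(test),
            )
        )
        # plug in the inner chart, rescaled to the nested axis and centred
        for prim in inner[test].primitives:
            if prim.tags.get("role") == "pool_label":
                continue  # the host label already names the test
            q = prim.transformed(1.0 / rs, cx, cy)
            q.tags["layer"] = "nested"
            q.tags["test"] = test
            scene.add(q)

    # test-level correlations along chords
    if n >= 2:
        corr = gtab.correlations.to_numpy()
        entries = []
        for i in range(n):
            for j in range(i + 1, n):
                a, b = test_center[tests[i]], test_center[tests[j]]
                mx, my = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
                dxv, dyv = b[0] - a[0], b[1] - a[1]
                norm = math.hypot(dxv, dyv) or 1.0
                entries.append(
                    (
                        float(corr[i, j]),
                        (mx, my),
                        (-dyv / norm, dxv / norm),
                        {"role": "correlation", "factors": (tests[i], tests[j]),
                         "value": float(corr[i, j]), "layer": "global"},
                    )
                )
        _place_value_texts(
            scene,
            entries,
            min_dist=max(0.35 * gtick, 0.1 * R_out),
            style={"fontsize": 10.0 * config.size_values * config.size,
                   "color": config.color("text")},
        )

    # cross-test facet arrows
    if config.show_xarrows:
        wanted: Sequence[XArrow]
        if config.xarrows is not None:
            keys = {frozenset(pair) for pair in config.xarrows}
            by_key = {
                frozenset((r.facet_a, r.facet_b)): XArrow(
                    r.facet_a, r.facet_b, r.test_a, r.test_b,
                    float(r.r_facets), float(r.r_tests),
                )
                for r in bundle.cross_test_correlations.itertuples(index=False)
            }
            wanted = [by_key[k] for k in keys if k in by_key]
        else:
            wanted = bundle.xarrows
        facet_pos: dict[str, tuple[float, float, float]] = {}
        for prim in scene.filter(kind="circle", role="facet_circle"):
            if prim.tags.get("layer") == "nested":
                facet_pos[prim.tags["factor"]] = (
                    prim.coords["x"], prim.coords["y"], prim.coords["r"]
                )
        for xa in wanted:
            if xa.facet_a not in facet_pos or xa.facet_b not in facet_pos:
                continue
            ax, ay, ar = facet_pos[xa.facet_a]
            bx, by, br = facet_pos[xa.facet_b]
            d = math.hypot(bx - ax, by - ay) or 1.0
            ux, uy = (bx - ax) / d, (by - ay) / d
            x1, y1 = ax + ux * ar, ay + uy * ar
            x2, y2 = bx - ux * br, by - uy * br
            scene.add(
                Primitive(
                    "arrow",
                    {"x1": x1, "y1": y1, "x2": x2, "y2": y2},
                    {"color": config.color("arrow"), "lw": 1.4 * config.width_arrows * config.size,
                     "ls": ":"},
                    {"role": "xarrow", "factors": (xa.facet_a, xa.facet_b),
                     "value": xa.r_facets, "r_tests": xa.r_tests},
                )
            )
            scene.add(
                Primitive(
                    "text",
                    {"x": (x1 + x2) / 2.0, "y": (y1 + y2) / 2.0},
                    {"fontsize": 9.0 * config.size_values * config.size,
                     "color": config.color("arrow")},
                    {"role": "xarrow_label", "factors": (xa.facet_a, xa.facet_b),
                     "value": xa.r_facets},
                    text=_fmt_r(xa.r_facets),
                )
            )

    ext = R_out * 1.1
    scene.extent = (-ext, ext, -ext, ext)
    return scene


_MODEL_LEVEL_COLOR_KEY = {"global": "global", "tests": "tests", "facets": "facets"}


def layout_item_overview(
    fits,
    naming,
    config: ChartConfig | None = None,
    squared: bool = True,
    tests: Sequence[str] | None = None,
    facets: Sequence[str] | None = None,
) -> SceneGraph:
    """Grid of per-item mini bar charts of (squared) loadings across models.

    One panel per item, one bar per fitted model (colors follow the nested
    chart's layer palette), rows grouped by test then facet.  ``tests`` /
    ``facets`` restrict the grid to a subset.
    """
    from .naming import facet_factor_name  # local import to avoid cycle noise

    config = config or ChartConfig(chart_type="overview")
    n_models = len(fits)
    if n_models not in (2, 3):
        raise ChartConfigError("item overview needs 2 or 3 fitted models")

    if naming.has_facets:
        groups = [
            (t, f, naming.items_of_facet(t, f))
            for t in naming.tests
            for f in naming.facets_of(t)
        ]
        if facets is not None:
            fac = set(facets)
            groups = [
                g for g in groups
                if g[1] in fac or facet_factor_name(naming, g[0], g[1]) in fac
            ]
    else:
        groups = [(t, None, naming.items_of_test(t)) for t in naming.tests]
    if tests is not None:
        tset = set(tests)
        groups = [g for g in groups if g[0] in tset]
    if not groups:
        raise ChartConfigError("no items selected for the overview")

    panel_w, panel_h, gap = 1.0, 1.0, 0.35
    bar_w = 0.8 * panel_w / n_models
    scene = SceneGraph(meta={"chart_type": "overview", "squared": squared,
                             "n_models": n_models})
    max_cols = max(len(g[2]) for g in groups)
    for row, (test, facet, row_items) in enumerate(groups):
        y0 = -row * (panel_h + gap)
        row_label = test if facet is None else f"{test} / {facet}"
        scene.add(
            Primitive(
                "text",
                {"x": -0.9 * panel_w, "y": y0 + 0.5 * panel_h},
                {"fontsize": 10.0 * config.size_text * config.size,
                 "color": config.color("text")},
                {"role": "group_label", "test": test, "facet": facet},
                text=config.label(row_label),
            )
        )
        for coli, it in enumerate(row_items):
            x0 = coli * (panel_w + gap)
            scene.add(
                Primitive(
                    "ray",
                    {"x1": x0, "y1": y0, "x2": x0 + panel_w, "y2": y0},
                    {"color": config.color("text"), "lw": 0.8 * config.size},
                    {"role": "panel_baseline", "item": it.column},
                )
            )
            scene.add(
                Primitive(
                    "text",
                    {"x": x0 + 0.5 * panel_w, "y": y0 + panel_h * 1.08},
                    {"fontsize": 7.0 * config.size_text * config.size,
                     "color": config.color("text")},
                    {"role": "item_label", "item": it.column},
                    text=config.label(it.item),
                )
            )
            for mj, fit in enumerate(fits):
                lam = fit.loading_of(it.column)
                h = lam * lam if squared else lam
                bx = x0 + 0.1 * panel_w + mj * bar_w
                scene.add(
                    Primitive(
                        "bar",
                        {"x": bx, "y": y0 if h >= 0 else y0 + h,
                         "w": bar_w * 0.92, "h": abs(h)},
                        {"color": config.color(_MODEL_LEVEL_COLOR_KEY[fit.model_level]),
                         "fill": True, "lw": 0.0},
                        {"role": "loading_bar", "item": it.column,
                         "model_level": fit.model_level, "value": h,
                         "loading": lam},
                    )
                )
                scene.add(
                    Primitive(
                        "text",
                        {"x": bx + 0.5 * bar_w * 0.92, "y": y0 - 0.12 * panel_h},
                        {"fontsize": 5.5 * config.size_text * config.size,
                         "color": config.color("text")},
                        {"role": "bar_label", "item": it.column,
                         "model_level": fit.model_level},
                        text=config.label(
                            str(fit.loadings.loc[it.column, "factor"])
                        ),
                    )
                )

    xmax = max_cols * (panel_w + gap)
    ymin = -len(groups) * (panel_h + gap)
    scene.extent = (-2.0 * panel_w, xmax, ymin, panel_h + gap)
    return scene


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_VECTOR_EXT = {".pdf", ".svg"}
_RASTER_EXT = {".png", ".jpeg", ".jpg"}


def render(scene: SceneGraph, config: ChartConfig | None = None, path: str | None = None) -> str:
    """Draw a scene graph to a file; format follows the extension.

    PDF and SVG stay fully vector; PNG/JPEG honor ``config.dpi``.  SVG
    output is byte-stable for identical scene + config (fixed hash salt, no
    date metadata).  ``zoom_x`` / ``zoom_y`` crop the viewport without
    rescaling geometry.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, FancyArrowPatch, Rectangle

    config = config or ChartConfig()
    path = path or config.file_name
    if not path:
        raise ChartConfigError("no output file name given")
    ext = "." + str(path).rsplit(".", 1)[-1].lower() if "." in str(path) else ""
    if ext not in _VECTOR_EXT | _RASTER_EXT:
        raise ChartConfigError(
            f"unsupported output format {ext or '(none)'}; use one of "
            "pdf, svg, png, jpeg"
        )

    xmin, xmax, ymin, ymax = scene.extent
    if config.zoom_x is not None:
        xmin, xmax = config.zoom_x
    if config.zoom_y is not None:
        ymin, ymax = config.zoom_y
    width = 8.0 * config.size
    height = width * (ymax - ymin) / (xmax - xmin)

    with plt.rc_context({"svg.hashsalt": "ipvis", "svg.fonttype": "path"}):
        fig = plt.figure(figsize=(width, height))
        ax = fig.add_axes([0, 0, 1, 1])
        ax.set_aspect("equal")
        ax.set_xlim(xmin, xmax)
        ax.set_ylim(ymin, ymax)
        ax.axis("off")

        for p in scene.primitives:
            s = p.style
            if p.kind == "circle":
                ax.add_patch(
                    Circle(
                        (p.coords["x"], p.coords["y"]),
                        p.coords["r"],
                        fill=bool(s.get("fill", False)),
                        facecolor=s.get("color") if s.get("fill") else "none",
                        edgecolor=s.get("color", "black"),
                        lw=s.get("lw", 1.0),
                        ls=s.get("ls", "-"),
                        alpha=s.get("alpha", 1.0),
                    )
                )
            elif p.kind in ("ray",):
                ax.plot(
                    [p.coords["x1"], p.coords["x2"]],
                    [p.coords["y1"], p.coords["y2"]],
                    color=s.get("color", "black"),
                    lw=s.get("lw", 1.0),
                    ls=s.get("ls", "-"),
                    alpha=s.get("alpha", 1.0),
                    solid_capstyle="round",
                )
            elif p.kind == "bar":
                ax.add_patch(
                    Rectangle(
                        (p.coords["x"], p.coords["y"]),
                        p.coords["w"],
                        p.coords["h"],
                        facecolor=s.get("color", "black"),
                        edgecolor="none",
                        alpha=s.get("alpha", 1.0),
                    )
                )
            elif p.kind == "arrow":
                ax.add_patch(
                    FancyArrowPatch(
                        (p.coords["x1"], p.coords["y1"]),
                        (p.coords["x2"], p.coords["y2"]),
                        arrowstyle="-|>",
                        mutation_scale=10.0 * config.size,
                        color=s.get("color", "black"),
                        lw=s.get("lw", 1.0),
                        ls=s.get("ls", "-"),
                    )
                )
            elif p.kind == "text":
                ax.text(
                    p.coords["x"],
                    p.coords["y"],
                    p.text or "",
                    ha="center",
                    va="center",
                    fontsize=s.get("fontsize", 10.0),
                    color=s.get("color", "black"),
                    alpha=s.get("alpha", 1.0),
                )
            elif p.kind == "arc":  # pragma: no cover - not emitted by layouts yet
                from matplotlib.patches import Arc

                ax.add_patch(
                    Arc(
                        (p.coords["x"], p.coords["y"]),
                        2 * p.coords["r"],
                        2 * p.coords["r"],
                        theta1=p.coords.get("theta1", 0.0),
                        theta2=p.coords.get("theta2", 360.0),
                        color=s.get("color", "black"),
                        lw=s.get("lw", 1.0),
                        ls=s.get("ls", "-"),
                    )
                )

        save_kwargs: dict = {}
        if ext == ".svg":
            save_kwargs["metadata"] = {"Date": None}
        elif ext == ".pdf":
            save_kwargs["metadata"] = {"CreationDate": None}
        elif ext in (".png", ".jpeg", ".jpg"):
            save_kwargs["dpi"] = config.dpi
        fig.savefig(path, **save_kwargs)
        plt.close(fig)
    return str(path)


# ---------------------------------------------------------------------------
# one-call chart functions
# ---------------------------------------------------------------------------

def _resolve_table(bundle: EstimatesBundle, test: str | None) -> tuple[CenterDistanceTable, str]:
    if test is None:
        return bundle.global_table, bundle.pool_name
    if test not in bundle.test_tables:
        raise ChartConfigError(
            f"unknown test {test!r}; available: {list(bundle.test_tables)}"
        )
    return bundle.test_tables[test], test


def facet_chart(
    bundle: EstimatesBundle,
    test: str | None = None,
    config: ChartConfig | None = None,
    **overrides,
) -> SceneGraph:
    """Facet chart of the whole pool (``test=None``) or of one test."""
    config = _with_overrides(config, chart_type="facet", **overrides)
    table, title = _resolve_table(bundle, test)
    if config.cd_method is None:
        config.cd_method = bundle.cd_method
    layer = "global" if test is None else "tests"
    ckey = "tests" if test is None else "facets"
    scene = layout_facet_chart(table, config, title=title, layer=layer, circle_color_key=ckey)
    if config.file_name:
        render(scene, config)
    return scene


def item_chart(
    bundle: EstimatesBundle,
    test: str | None = None,
    config: ChartConfig | None = None,
    **overrides,
) -> SceneGraph:
    """Item chart of the whole pool or of one test's items."""
    config = _with_overrides(config, chart_type="item", **overrides)
    table, title = _resolve_table(bundle, test)
    scene = layout_item_chart(table, config, title=title)
    if config.file_name:
        render(scene, config)
    return scene


def nested_chart(
    bundle: EstimatesBundle,
    config: ChartConfig | None = None,
    **overrides,
) -> SceneGraph:
    """Nested chart: the global facet chart with inner per-test facet charts."""
    config = _with_overrides(config, chart_type="nested", **overrides)
    scene = layout_nested_chart(bundle, config)
    if config.file_name:
        render(scene, config)
    return scene


def item_overview(
    bundle: EstimatesBundle,
    naming=None,
    config: ChartConfig | None = None,
    squared: bool = True,
    tests: Sequence[str] | None = None,
    facets: Sequence[str] | None = None,
    **overrides,
) -> SceneGraph:
    """Bar-chart overview of every item's (squared) loadings across models."""
    from .naming import parse_columns

    config = _with_overrides(config, chart_type="overview", **overrides)
    if naming is None:
        naming = parse_columns(
            list(bundle.global_table.items.index), bundle.pool_name
        )
    scene = layout_item_overview(
        bundle.raw, naming, config, squared=squared, tests=tests, facets=facets
    )
    if config.file_name:
        render(scene, config)
    return scene


def _with_overrides(config: ChartConfig | None, **overrides) -> ChartConfig:
    if config is None:
        config = ChartConfig(chart_type=overrides.pop("chart_type", "facet"))
    else:
        overrides.pop("chart_type", None)
        config = ChartConfig(**{**asdict(config)})
    for k, v in overrides.items():
        if not hasattr(config, k):
            raise ChartConfigError(f"unknown chart option {k!r}")
        setattr(config, k, v)
    config.__post_init__()
    return config
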