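"""Chart geometry: scene-graph layouts and file rendering."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipvis.center_distance import CenterDistanceTable, build_estimates
from ipvis.charts import (
    ChartConfig,
    choose_axis_tick,
    facet_chart,
    item_chart,
    item_overview,
    layout_facet_chart,
    layout_item_chart,
    layout_nested_chart,
    nested_chart,
    render,
)
from ipvis.exceptions import (
    ChartConfigError,
    ChartLayoutWarning,
    RelativeScalingWarning,
)
from ipvis.naming import parse_columns

from conftest import make_fit_result


def make_table(cds: dict[str, float], items_per_factor: int = 2) -> CenterDistanceTable:
    """Center-distance table whose aggregate cds equal the given values."""
    rows, index = [], []
    for fac, cd in cds.items():
        ls = math.sqrt(0.25 * (1.0 + cd)) if cd > -1 else 0.0
        for i in range(items_per_factor):
            index.append(f"{fac}_it{i}")
            rows.append(
                {
                    "factor": fac,
                    "lambda_general": 0.5,
                    "lambda_specific": ls,
                    "cd_raw": max(cd, 0.0),
                    "cd_display": max(cd, 0.0),
                }
            )
    items = pd.DataFrame(rows, index=pd.Index(index, name="item"))
    names = list(cds)
    summaries = pd.DataFrame(
        {"mean_cd": [max(c, 0.0) for c in cds.values()], "aggregate_cd": list(cds.values())},
        index=pd.Index(names, name="factor"),
    )
    k = len(names)
    corr = np.full((k, k), 0.3)
    np.fill_diagonal(corr, 1.0)
    return CenterDistanceTable(
        items=items,
        summaries=summaries,
        correlations=pd.DataFrame(corr, index=names, columns=names),
        comparison=("tests", "facets"),
    )


def edge_distance(prim) -> float:
    """Nearest-edge distance of a facet circle from the chart center."""
    return math.hypot(prim.coords["x"], prim.coords["y"]) - prim.coords["r"]


class TestAxisTick:
    @pytest.mark.parametrize(
        "max_cd, tick",
        [(1.0, 0.5), (0.9, 0.2), (4.0, 2.0), (0.25, 0.1), (12.0, 5.0), (0.0, 0.1)],
    )
    def test_largest_1_2_5_not_exceeding_half_max(self, max_cd, tick):
        assert choose_axis_tick(max_cd) == tick


class TestFacetChartLayout:
    def test_edge_distances_proportional_to_cds(self):
        scene = layout_facet_chart(make_table({"A": 1.0, "B": 0.5}))
        circles = {p.tags["factor"]: p for p in scene.filter("circle", "facet_circle")}
        assert edge_distance(circles["A"]) == pytest.approx(
            2 * edge_distance(circles["B"]), abs=1e-9
        )

    def test_zero_cds_put_circles_tangent_to_center(self):
        scene = layout_facet_chart(make_table({"A": 0.0, "B": 0.0, "C": 0.0}))
        for p in scene.filter("circle", "facet_circle"):
            assert edge_distance(p) == pytest.approx(0.0, abs=1e-12)

    def test_four_facets_print_six_correlations_once_each(self):
        scene = layout_facet_chart(make_table({"A": 1.0, "B": 0.8, "C": 0.6, "D": 0.4}))
        texts = scene.filter("text", "correlation")
        assert len(texts) == 6
        assert len({frozenset(p.tags["factors"]) for p in texts}) == 6

    def test_negative_aggregate_cd_drawn_at_zero_and_flagged(self):
        scene = layout_facet_chart(make_table({"A": -0.3, "B": 0.5}))
        circ = {p.tags["factor"]: p for p in scene.filter("circle", "facet_circle")}
        assert circ["A"].tags["truncated"] is True
        assert edge_distance(circ["A"]) == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_circles_warn_with_suggestion(self):
        with pytest.warns(ChartLayoutWarning, match="subradius"):
            layout_facet_chart(
                make_table({f"F{i}": 0.02 * i for i in range(8)}),
                ChartConfig(subradius=0.5),
            )


class TestItemChartLayout:
    def test_marker_radii_equal_cds(self):
        table = make_table({"A": 1.0}, items_per_factor=3)
        table.items["cd_display"] = [0.0, 1.0, 2.0]
        scene = layout_item_chart(table)
        radii = sorted(
            math.hypot(p.coords["x"], p.coords["y"])
            for p in scene.filter("circle", "item_marker")
        )
        assert radii == pytest.approx([0.0, 1.0, 2.0], abs=1e-9)

    def test_outlier_grows_extent_beyond_ticks(self):
        table = make_table({"A": 1.0}, items_per_factor=3)
        table.items["cd_display"] = [0.2, 0.3, 9.0]
        scene = layout_item_chart(table)
        assert scene.extent[1] > 9.0
        assert max(p.tags["value"] for p in scene.filter("circle", "item_marker")) == 9.0

    def test_items_stay_within_their_sector(self):
        table = make_table({"A": 0.8, "B": 0.6}, items_per_factor=10)
        scene = layout_item_chart(table)
        # sector of A is centred at 12 o'clock spanning pi; all A markers above x-axis
        for p in scene.filter("circle", "item_marker"):
            if p.tags["factor"] == "A" and p.tags["value"] > 0:
                assert p.coords["y"] > -1e-12
        assert len([p for p in scene.filter("ray", "item_ray")]) == 20


class TestNestedChartLayout:
    def test_equal_axis_scale_at_relative_scaling_one(self, small_pop_bundle):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = layout_nested_chart(
                small_pop_bundle, ChartConfig(relative_scaling=1.0)
            )
        for p in scene.primitives:
            if p.tags.get("role") == "cd_bar":
                assert p.tags["axis_scale"] == pytest.approx(1.0)
                bar_len = math.hypot(
                    p.coords["x2"] - p.coords["x1"], p.coords["y2"] - p.coords["y1"]
                )
                assert bar_len == pytest.approx(p.tags["value"], abs=1e-9)

    def test_doubling_relative_scaling_halves_nested_layer_only(self, small_pop_bundle):
        def scenes(rs):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return layout_nested_chart(
                    small_pop_bundle, ChartConfig(relative_scaling=rs)
                )

        s1, s2 = scenes(1.5), scenes(3.0)
        bars1 = [p for p in s1.primitives if p.tags.get("role") == "cd_bar"]
        bars2 = [p for p in s2.primitives if p.tags.get("role") == "cd_bar"]
        for a, b in zip(bars1, bars2):
            assert a.tags["factor"] == b.tags["factor"]
            if a.tags.get("layer") == "global":
                assert a.coords == b.coords  # global layer untouched
            else:
                assert b.tags["axis_scale"] == pytest.approx(a.tags["axis_scale"] / 2)
                assert b.tags["radial"] == pytest.approx(a.tags["radial"] / 2)

    def test_xarrow_primitives_iff_facet_exceeds_test_correlation(self):
        cols = [f"{t}_{f}_i{i}" for t, f in (("X", "Soci"), ("X", "Live"), ("O", "Crea"), ("O", "AesA")) for i in (1, 2)]
        naming = parse_columns(cols, "P")
        g = make_fit_result({c: ("P", 0.5) for c in cols}, model_level="global")
        tcorr = pd.DataFrame([[1, 0.29], [0.29, 1]], index=["X", "O"], columns=["X", "O"])
        t = make_fit_result(
            {c: (c.split("_")[0], 0.6) for c in cols}, correlations=tcorr,
            model_level="tests",
        )
        facs = ["Soci", "Live", "Crea", "AesA"]
        fc = np.full((4, 4), 0.2)
        fc[facs.index("Soci"), facs.index("Crea")] = 0.36
        fc[facs.index("Crea"), facs.index("Soci")] = 0.36
        fc[:2, :2] = fc[2:, 2:] = 0.5
        np.fill_diagonal(fc, 1.0)
        f = make_fit_result(
            {c: (c.split("_")[1], 0.7) for c in cols},
            correlations=pd.DataFrame(fc, index=facs, columns=facs),
            model_level="facets",
        )
        bundle = build_estimates([g, t, f], naming)
        assert [(x.facet_a, x.facet_b) for x in bundle.xarrows] == [("Soci", "Crea")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = layout_nested_chart(bundle, ChartConfig())
        arrows = scene.filter("arrow", "xarrow")
        assert len(arrows) == 1
        assert arrows[0].tags["value"] == pytest.approx(0.36)
        assert arrows[0].tags["value"] > arrows[0].tags["r_tests"]

    def test_more_compact_test_gets_smaller_circle(self, preset_pop_bundle):
        # compare enclosing circle radii of the two inner charts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = layout_nested_chart(preset_pop_bundle, ChartConfig())
        host = {
            p.tags["factor"]: p.coords["r"]
            for p in scene.filter("circle", "facet_circle")
            if p.tags.get("layer") == "global"
        }
        max_cd = {
            t: preset_pop_bundle.test_tables[t].summaries["aggregate_cd"].max()
            for t in ("H", "A")
        }
        assert (host["H"] > host["A"]) == (max_cd["H"] > max_cd["A"])

    def test_nested_requires_facet_level(self):
        cols = ["A_1", "A_2", "B_1", "B_2"]
        naming = parse_columns(cols, "P")
        g = make_fit_result({c: ("P", 0.5) for c in cols}, model_level="global")
        t = make_fit_result(
            {c: (c.split("_")[0], 0.6) for c in cols}, model_level="tests"
        )
        bundle = build_estimates([g, t], naming)
        with pytest.raises(ChartConfigError):
            layout_nested_chart(bundle, ChartConfig())

    def test_non_unit_scaling_warns_readers(self, small_pop_bundle):
        with pytest.warns(RelativeScalingWarning):
            layout_nested_chart(small_pop_bundle, ChartConfig(relative_scaling=2.0))

    def test_underscaled_nested_chart_warns_with_suggestion(self, small_pop_bundle):
        with pytest.warns(ChartLayoutWarning, match="relative_scaling"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                layout_nested_chart(small_pop_bundle, ChartConfig(relative_scaling=0.25))


class TestItemOverview:
    def test_bar_heights_are_squared_loadings(self, small_pop_bundle):
        naming = parse_columns(
            list(small_pop_bundle.global_table.items.index), "P"
        )
        scene = item_overview(small_pop_bundle, naming=naming)
        col = small_pop_bundle.global_table.items.index[0]
        bars = [
            p for p in scene.filter("bar", "loading_bar") if p.tags["item"] == col
        ]
        assert len(bars) == 3
        for p in bars:
            assert p.coords["h"] == pytest.approx(p.tags["loading"] ** 2)

    def test_unsquared_heights_are_loadings(self, small_pop_bundle):
        scene = item_overview(small_pop_bundle, squared=False)
        for p in scene.filter("bar", "loading_bar")[:6]:
            assert p.coords["h"] == pytest.approx(abs(p.tags["loading"]))

    def test_two_model_bundle_gives_two_bars_per_item(self):
        cols = ["A_1", "A_2", "B_1", "B_2"]
        naming = parse_columns(cols, "P")
        g = make_fit_result({c: ("P", 0.5) for c in cols}, model_level="global")
        t = make_fit_result({c: (c.split("_")[0], 0.6) for c in cols}, model_level="tests")
        bundle = build_estimates([g, t], naming)
        scene = item_overview(bundle, naming=naming)
        bars = scene.filter("bar", "loading_bar")
        assert len(bars) == 2 * len(cols)

    def test_facet_subset_restricts_panels(self, small_pop_bundle, small_model):
        scene = item_overview(
            small_pop_bundle, naming=small_model.naming, facets=["F11"]
        )
        assert len(scene.filter("text", "item_label")) == 3


class TestLabelCompleteness:
    def test_every_factor_and_item_labelled_once_after_relabel(self, small_pop_bundle):
        relabel = {"F11": "Warmth", "T1": "First"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = layout_nested_chart(small_pop_bundle, ChartConfig(relabel=relabel))
        labels = [p.text for p in scene.filter("text", "facet_label")]
        expected = {"First", "T2", "Warmth", "F12", "F21", "F22"}
        assert sorted(labels) == sorted(expected)
        pool = [p.text for p in scene.filter("text", "pool_label")]
        assert pool == ["P"]


@st.composite
def cd_maps(draw):
    n = draw(st.integers(2, 7))
    return {
        f"F{i}": draw(st.floats(0.0, 5.0, allow_nan=False)) for i in range(n)
    }


@given(cd_maps())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_property_radial_fidelity(cds):
    """Edge distance over tick radius equals cd over tick value, everywhere."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ChartLayoutWarning)
        scene = layout_facet_chart(make_table(cds))
    tick = scene.meta["tick"]
    for p in scene.filter("circle", "facet_circle"):
        assert edge_distance(p) / tick == pytest.approx(
            p.tags["value"] / tick, abs=1e-9
        )
    for p in scene.filter("ray", "cd_bar"):
        length = math.hypot(p.coords["x2"] - p.coords["x1"], p.coords["y2"] - p.coords["y1"])
        assert length == pytest.approx(p.tags["value"] * p.tags["axis_scale"], abs=1e-9)


class TestRender:
    def test_pdf_and_svg_are_vector_png_jpeg_raster(self, small_pop_bundle, tmp_path):
        scene = facet_chart(small_pop_bundle, test="T1")
        for ext in ("pdf", "svg", "png", "jpeg"):
            out = tmp_path / f"chart.{ext}"
            render(scene, ChartConfig(dpi=72), str(out))
            assert out.stat().st_size > 0
        head = (tmp_path / "chart.svg").read_bytes()[:200]
        assert b"<?xml" in head or b"<svg" in head
        assert (tmp_path / "chart.pdf").read_bytes()[:5] == b"%PDF-"

    def test_svg_output_is_byte_identical_across_runs(self, small_pop_bundle, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scene = nested_chart(small_pop_bundle)
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render(scene, ChartConfig(), str(a))
        render(scene, ChartConfig(), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_dpi_scales_pixel_dimensions(self, small_pop_bundle, tmp_path):
        from PIL import Image

        scene = facet_chart(small_pop_bundle, test="T1")
        lo, hi = tmp_path / "lo.png", tmp_path / "hi.png"
        render(scene, ChartConfig(dpi=72), str(lo))
        render(scene, ChartConfig(dpi=300), str(hi))
        wlo = Image.open(lo).size[0]
        whi = Image.open(hi).size[0]
        assert whi == pytest.approx(wlo * 300 / 72, abs=2)

    def test_zoom_crops_viewport(self, small_pop_bundle, tmp_path):
        from PIL import Image

        scene = facet_chart(small_pop_bundle, test="T1")
        full, half = tmp_path / "full.png", tmp_path / "half.png"
        render(scene, ChartConfig(dpi=72), str(full))
        xmax = scene.extent[1]
        render(scene, ChartConfig(dpi=72, zoom_x=(0.0, xmax)), str(half))
        # same rendered width per data unit is not required, but the aspect
        # ratio must reflect the halved x-range
        wf, hf = Image.open(full).size
        wh, hh = Image.open(half).size
        assert hh / wh == pytest.approx(2 * hf / wf, rel=0.05)

    def test_unsupported_extension_rejected(self, small_pop_bundle, tmp_path):
        scene = facet_chart(small_pop_bundle, test="T1")
        with pytest.raises(ChartConfigError, match="format"):
            render(scene, ChartConfig(), str(tmp_path / "chart.tiff"))

    def test_scene_json_export(self, small_pop_bundle, tmp_path):
        import json

        scene = facet_chart(small_pop_bundle, test="T1")
        path = tmp_path / "scene.json"
        scene.to_json(path)
        data = json.loads(path.read_text())
        assert data["extent"] == list(scene.extent)
        assert len(data["primitives"]) == len(scene.primitives)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"subradius": -0.1},
            {"relative_scaling": 0.0},
            {"zoom_x": (1.0, 1.0)},
            {"zoom_y": (2.0, -1.0)},
            {"dpi": 0},
            {"size": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ChartConfigError):
            ChartConfig(**kwargs)

    def test_unknown_override_rejected(self, small_pop_bundle):
        with pytest.raises(ChartConfigError, match="unknown chart option"):
            facet_chart(small_pop_bundle, test="T1", no_such_option=1)
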