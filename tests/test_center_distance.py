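"""The center-distance statistics and the estimates bundle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipvis.center_distance import (
    EstimatesBundle,
    aggregate_center_distance,
    build_estimates,
    detect_xarrows,
    item_center_distance,
    mean_center_distance,
)
from ipvis.exceptions import StructuralError, UnboundedCenterDistanceWarning
from ipvis.naming import parse_columns

from conftest import make_fit_result


class TestItemCenterDistance:
    @pytest.mark.parametrize(
        "lg, ls, expected",
        [
            (0.4, 0.8, 3.0),  # doubling the loading quadruples explained variance
            (0.6, 0.8, 0.78),
            (0.8, 0.4, 0.0),  # specific does worse: gated to zero
            (0.5, 0.5, 0.0),
            (-0.06, 0.16, 6.11),  # misfitting item: small loadings, huge ratio
        ],
    )
    def test_worked_values(self, lg, ls, expected):
        cd_raw, cd_display = item_center_distance(lg, ls)
        assert round(cd_raw, 2) == expected
        assert round(cd_display, 2) == expected

    def test_gate_uses_absolute_loadings(self):
        # sign alone must not zero the statistic
        assert item_center_distance(-0.2, 0.4)[0] == pytest.approx(3.0)
        assert item_center_distance(0.2, -0.4)[0] == pytest.approx(3.0)
        assert item_center_distance(-0.4, 0.2)[0] == 0.0

    def test_zero_general_loading_is_capped_with_warning(self):
        with pytest.warns(UnboundedCenterDistanceWarning):
            cd_raw, cd_display = item_center_distance(0.0, 0.5, cap=50.0)
        assert cd_raw == cd_display == 50.0

    def test_both_zero_is_zero(self):
        assert item_center_distance(0.0, 0.0) == (0.0, 0.0)


class TestPoolSummaries:
    def test_two_item_worked_example(self):
        pairs = [(0.1, 0.2), (0.6, 0.8)]
        assert round(aggregate_center_distance(pairs), 2) == 0.84
        assert round(mean_center_distance(pairs), 2) == 1.89

    def test_single_pair_reduces_to_item_cd(self):
        assert aggregate_center_distance([(0.4, 0.8)]) == pytest.approx(3.0)
        assert mean_center_distance([(0.4, 0.8)]) == pytest.approx(3.0)

    def test_no_gain_is_zero(self):
        pairs = [(0.5, 0.5), (0.5, 0.5)]
        assert aggregate_center_distance(pairs) == pytest.approx(0.0)
        assert mean_center_distance(pairs) == pytest.approx(0.0)

    def test_aggregate_can_be_negative_mean_cannot(self):
        pairs = [(0.8, 0.4), (0.5, 0.52)]
        assert aggregate_center_distance(pairs) < 0
        assert mean_center_distance(pairs) >= 0

    def test_all_zero_general_loadings_capped(self):
        with pytest.warns(UnboundedCenterDistanceWarning):
            assert aggregate_center_distance([(0.0, 0.4)], cap=10.0) == 10.0


@given(
    st.lists(
        st.tuples(
            st.floats(-0.95, 0.95),
            st.floats(-0.95, 0.95),
        ),
        min_size=1,
        max_size=12,
    )
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_property_aggregate_matches_naive_loop_oracle(pairs):
    """Eq.-by-definition check: sum of squares computed by an explicit loop."""
    num = den = 0.0
    for lg, ls in pairs:
        num += ls * ls
        den += lg * lg
    if den < 1e-12 * len(pairs):
        return
    expected = num / den - 1.0
    if expected > 100.0:  # display cap region
        return
    assert aggregate_center_distance(pairs) == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(st.tuples(st.floats(0.1, 0.9), st.floats(0.1, 0.9)), min_size=2, max_size=8),
    st.integers(0, 7),
    st.floats(0.01, 0.09),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_property_aggregate_monotone_in_specific_loadings(pairs, idx, bump):
    """Increasing any one specific loading never decreases the aggregate."""
    idx = idx % len(pairs)
    before = aggregate_center_distance(pairs)
    bumped = list(pairs)
    lg, ls = bumped[idx]
    bumped[idx] = (lg, ls + bump)
    assert aggregate_center_distance(bumped) >= before - 1e-12


@given(
    st.lists(st.tuples(st.floats(-1, 1), st.floats(-1, 1)), min_size=1, max_size=10)
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_property_display_cd_never_negative(pairs):
    import warnings as _w

    for lg, ls in pairs:
        with _w.catch_warnings():
            _w.simplefilter("ignore", UnboundedCenterDistanceWarning)
            _, cd_display = item_center_distance(lg, ls)
        assert cd_display >= 0.0


def _two_level_fits():
    """Hand-made global + tests fits over 2 tests x 2 items."""
    cols = ["A_1", "A_2", "B_1", "B_2"]
    g = make_fit_result(
        {c: ("P", lam) for c, lam in zip(cols, (0.5, 0.6, 0.55, 0.45))},
        model_level="global",
    )
    corr = pd.DataFrame([[1, 0.29], [0.29, 1]], index=["A", "B"], columns=["A", "B"])
    t = make_fit_result(
        {
            "A_1": ("A", 0.7),
            "A_2": ("A", 0.65),
            "B_1": ("B", 0.6),
            "B_2": ("B", 0.8),
        },
        correlations=corr,
        model_level="tests",
    )
    return parse_columns(cols, "P"), [g, t]


class TestBuildEstimates:
    def test_two_model_bundle_has_global_table_only(self):
        naming, fits = _two_level_fits()
        bundle = build_estimates(fits, naming)
        assert not bundle.has_facets
        assert bundle.test_tables == {}
        assert list(bundle.global_table.summaries.index) == ["A", "B"]
        row = bundle.global_table.items.loc["A_1"]
        assert row["cd_raw"] == pytest.approx(0.7**2 / 0.5**2 - 1)

    def test_item_mismatch_across_models_is_structural_error(self):
        naming, fits = _two_level_fits()
        fits[1].loadings.rename(index={"A_1": "A_9"}, inplace=True)
        with pytest.raises(StructuralError):
            build_estimates(fits, naming)

    def test_specific_gain_everywhere_gives_positive_aggregate_cds(
        self, small_pop_bundle
    ):
        # facet loadings uniformly exceed population test-level loadings
        for table in small_pop_bundle.test_tables.values():
            assert (table.summaries["aggregate_cd"] > 0).all()

    def test_low_loading_outlier_inflates_mean_but_not_aggregate(self):
        cols = ["T_a", "T_b", "T_c"]
        naming = parse_columns(cols, "P")
        g = make_fit_result(
            {"T_a": ("P", 0.6), "T_b": ("P", 0.7), "T_c": ("P", 0.02)},
            model_level="global",
        )
        s = make_fit_result(
            {"T_a": ("T", 0.7), "T_b": ("T", 0.75), "T_c": ("T", 0.2)},
            model_level="tests",
        )
        bundle = build_estimates([g, s], naming)
        summ = bundle.global_table.summaries.loc["T"]
        assert summ["mean_cd"] > 10 * summ["aggregate_cd"]

    def test_bundle_json_round_trip(self, small_sample_bundle):
        text = small_sample_bundle.to_json()
        back = EstimatesBundle.from_json(text)
        pd.testing.assert_frame_equal(
            back.global_table.items, small_sample_bundle.global_table.items
        )
        for t in small_sample_bundle.test_tables:
            pd.testing.assert_frame_equal(
                back.test_tables[t].summaries,
                small_sample_bundle.test_tables[t].summaries,
            )
        assert [x.to_dict() for x in back.xarrows] == [
            x.to_dict() for x in small_sample_bundle.xarrows
        ]


class TestDetectXarrows:
    def _bundle_with(self, r_facets: float, r_tests: float) -> EstimatesBundle:
        cols = [f"{t}_{f}_i{i}" for t, f in (("X", "Soci"), ("O", "Crea")) for i in (1, 2)]
        naming = parse_columns(cols, "P")
        g = make_fit_result({c: ("P", 0.5) for c in cols}, model_level="global")
        tcorr = pd.DataFrame(
            [[1, r_tests], [r_tests, 1]], index=["X", "O"], columns=["X", "O"]
        )
        t = make_fit_result(
            {c: (c.split("_")[0], 0.6) for c in cols},
            correlations=tcorr,
            model_level="tests",
        )
        fcorr = pd.DataFrame(
            [[1, r_facets], [r_facets, 1]],
            index=["Soci", "Crea"],
            columns=["Soci", "Crea"],
        )
        f = make_fit_result(
            {c: (c.split("_")[1], 0.7) for c in cols},
            correlations=fcorr,
            model_level="facets",
        )
        return build_estimates([g, t, f], naming)

    def test_facet_pair_above_test_pair_is_flagged(self):
        bundle = self._bundle_with(r_facets=0.36, r_tests=0.29)
        assert len(bundle.xarrows) == 1
        xa = bundle.xarrows[0]
        assert (xa.r_facets, xa.r_tests) == (0.36, 0.29)

    def test_equality_is_excluded(self):
        assert self._bundle_with(0.30, 0.30).xarrows == []

    def test_all_below_gives_empty_list(self):
        assert self._bundle_with(0.10, 0.29).xarrows == []

    def test_sorted_descending_by_facet_correlation(self, preset_pop_bundle):
        rs = [x.r_facets for x in detect_xarrows(preset_pop_bundle)]
        assert rs == sorted(rs, reverse=True)
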