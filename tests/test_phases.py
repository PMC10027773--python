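"""Phase design: response-guided termination, matched triplets, the factorial study."""

import numpy as np
import pytest

from singlecase.generator import ConditionSpec, trend_angles
from singlecase.phases import (
    SCHEMES,
    StudyDesign,
    assign_random_lengths,
    build_graphs,
    build_study,
    response_guided_length,
    response_guided_lengths,
)


def _padded(head, n=30, fill=10.0):
    return np.array(list(head) + [fill] * (n - len(head)))


class TestResponseGuidedLength:
    def test_trend_stabilises_one_point_after_minimum(self):
        spec = ConditionSpec("trend", 3, 5, 0.0, 30.0)
        values = _padded([10, 12, 14, 10])  # slope over 4 points: 0.2 -> 11.3 deg
        assert response_guided_length(values, spec) == (4, False)

    def test_never_stable_series_is_capped(self):
        spec = ConditionSpec("trend", 3, 5, 0.0, 30.0)
        values = np.arange(30.0)  # 45-degree ramp throughout
        assert response_guided_length(values, spec) == (25, True)

    def test_variability_uses_last_three_points(self):
        spec = ConditionSpec("variability", 3, 5, 0.0, 1.0)
        values = _padded([10, 13, 7, 10.1, 10.0, 10.2])
        # SD of the last 3 points first drops to 0.1 at t = 6
        assert response_guided_length(values, spec) == (6, False)

    def test_batch_agrees_with_scalar(self, small_trend_study):
        ds = small_trend_study
        spec = ds.spec_for_row(ds.series.iloc[0])
        cell = ds.series[ds.series.cell_id == ds.series.cell_id.iloc[0]]
        vals = ds.values[cell.series_id.to_numpy()]
        lengths, capped = response_guided_lengths(vals, spec)
        for i in range(0, len(vals), 7):
            assert response_guided_length(vals[i], spec) == (lengths[i], capped[i])


class TestRandomLengths:
    def test_multiset_preserved(self):
        rng = np.random.default_rng(0)
        rg = rng.integers(4, 26, size=10_000)
        out = assign_random_lengths(rg, rng)
        assert sorted(out) == sorted(rg)

    def test_single_element_identity(self):
        assert assign_random_lengths([6], np.random.default_rng(0)).tolist() == [6]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_random_lengths([], np.random.default_rng(0))


class TestBuildGraphs:
    SPEC = ConditionSpec("trend", 3, 5, 0.0, 30.0, smd=3)

    def test_zero_effect_leaves_series_untouched(self):
        spec = ConditionSpec("trend", 3, 5, 0.0, 30.0, smd=0)
        values = np.random.default_rng(1).normal(10, 1, 30)
        for g in build_graphs(values, spec, 7, 5):
            L = len(g.phase_a)
            assert np.array_equal(g.phase_a, values[:L])
            assert np.array_equal(g.phase_b, values[L : L + 5])

    def test_effect_is_constant_phase_b_shift(self):
        values = _padded([10, 10, 10, 10.1, 9.8, 10.0, 10.3, 9.9])
        fixed, _, _ = build_graphs(values, self.SPEC, 7, 5)
        assert fixed.phase_b == pytest.approx([13.1, 12.8, 13.0, 13.3, 12.9])
        assert np.array_equal(fixed.phase_a, values[:3])

    def test_variability_effect_scaled_by_1_73(self):
        spec = ConditionSpec("variability", 3, 5, 0.0, 1.0, smd=2)
        values = np.full(30, 10.0)
        fixed, _, _ = build_graphs(values, spec, 7, 5)
        assert fixed.phase_b == pytest.approx(np.full(5, 13.46))

    def test_siblings_share_baseline_prefix_and_smd(self):
        values = np.random.default_rng(2).normal(10, 1, 30)
        graphs = build_graphs(values, self.SPEC, 9, 4)
        assert [g.scheme for g in graphs] == list(SCHEMES)
        prefix = graphs[0].phase_a
        for g in graphs[1:]:
            assert np.array_equal(g.phase_a[: len(prefix)], prefix)
            assert g.spec.smd == self.SPEC.smd

    def test_out_of_range_lengths_rejected(self):
        values = np.full(30, 10.0)
        with pytest.raises(ValueError):
            build_graphs(values, self.SPEC, 26, 5)  # 26 > 30 - n_b
        with pytest.raises(ValueError):
            build_graphs(values, self.SPEC, 7, 2)  # 2 < min_a


class TestBuildStudy:
    def test_design_shape_and_null_split(self, small_trend_study):
        ds = small_trend_study
        assert ds.n_series == 16 * 50
        assert ds.n_graphs == 3 * ds.n_series
        assert (ds.series.smd == 0).mean() == 0.5
        # uniform SMD allocation among effect series
        counts = ds.series[ds.series.smd > 0].smd.value_counts()
        assert set(counts) == {16 * 5}

    def test_counterbalancing_every_level_in_half_the_series(self, small_trend_study):
        series = small_trend_study.series
        for factor, levels in [
            ("min_a", (3, 5)),
            ("n_b", (5, 10)),
            ("autocorr", (0.0, 0.4)),
            ("stability_threshold", (15.0, 30.0)),
        ]:
            for level in levels:
                assert (series[factor] == level).mean() == 0.5

    def test_response_guided_exceeds_minimum_unless_capped(self, small_trend_study):
        s = small_trend_study.series
        cap = 30 - s.n_b
        uncapped = s[~s.rg_capped]
        assert (uncapped.rg_length > uncapped.min_a).all()
        assert (uncapped.rg_length <= cap[~s.rg_capped]).all()
        capped = s[s.rg_capped]
        assert (capped.rg_length == cap[s.rg_capped]).all()
        assert s.random_length.between(s.min_a, cap).all()

    def test_random_lengths_permuted_within_cells(self, small_trend_study):
        for _, cell in small_trend_study.series.groupby("cell_id"):
            assert sorted(cell.random_length) == sorted(cell.rg_length)

    def test_every_series_screens_unstable_at_minimum(self, small_trend_study):
        ds = small_trend_study
        for _, cell in ds.series.groupby("cell_id"):
            vals = ds.values[cell.series_id.to_numpy()]
            angles = trend_angles(vals[:, : cell.min_a.iloc[0]])
            assert (np.abs(angles) > cell.stability_threshold.iloc[0]).all()

    def test_initial_trend_sign_matches_recomputation(self, small_trend_study):
        ds = small_trend_study
        for _, cell in ds.series.groupby("cell_id"):
            vals = ds.values[cell.series_id.to_numpy()]
            angles = trend_angles(vals[:, : cell.min_a.iloc[0]])
            expected = np.where(angles >= 0, "increasing", "decreasing")
            assert (cell.initial_trend_sign.to_numpy() == expected).all()

    def test_generation_is_pure_function_of_seed(self):
        d = StudyDesign("variability", 10, 2, seed=5)
        ds1, ds2 = build_study(d), build_study(d)
        assert np.array_equal(ds1.values, ds2.values)
        assert ds1.series.equals(ds2.series)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            StudyDesign("trend", 10, 5, seed=0)
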