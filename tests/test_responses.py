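import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorbulb import (
    StimulusProtocol,
    assign_preference,
    build_response_table,
    category_counts,
    is_significant,
    lifetime_sparseness,
    response_magnitude,
    sort_population_heatmap,
    summarize_category_counts,
)
from odorbulb.responses import ResponseTable
from odorbulb.traces import TraceMatrix


class TestResponseMagnitude:
    def test_zero_trace_gives_zero(self, protocol):
        assert response_magnitude(np.zeros(protocol.n_frames), protocol) == 0.0

    def test_step_of_half(self, protocol):
        trace = np.zeros(protocol.n_frames)
        trace[protocol.onset_frame :] = 0.5
        assert response_magnitude(trace, protocol) == pytest.approx(0.5)

    def test_suppression_is_negative(self, protocol):
        trace = np.zeros(protocol.n_frames)
        trace[protocol.onset_frame :] = -0.3
        assert response_magnitude(trace, protocol) == pytest.approx(-0.3)

    def test_short_trace_rejected(self, protocol):
        with pytest.raises(ValueError, match="too short"):
            response_magnitude(np.zeros(protocol.onset_frame + 10), protocol)

    def test_uses_first_30_stimulus_frames_only(self, protocol):
        trace = np.zeros(protocol.n_frames)
        onset = protocol.onset_frame
        trace[onset : onset + 30] = 1.0
        trace[onset + 30 :] = -5.0  # outside the magnitude window
        assert response_magnitude(trace, protocol) == pytest.approx(1.0)


class TestIsSignificant:
    def _trace_with_baseline_noise(self, protocol, sd, peak, rng):
        trace = np.zeros(protocol.n_frames)
        trace[: protocol.onset_frame] = rng.normal(0, sd, protocol.onset_frame)
        trace[protocol.onset_frame + 10] = peak
        return trace

    def test_five_sd_peak_not_significant(self, protocol, rng):
        trace = self._trace_with_baseline_noise(protocol, 0.01, 0.05, rng)
        sig, z = is_significant(trace, protocol)
        assert not sig
        assert z < 6

    def test_ten_sd_peak_significant(self, protocol, rng):
        trace = self._trace_with_baseline_noise(protocol, 0.01, 0.10, rng)
        sig, z = is_significant(trace, protocol)
        assert sig
        assert z > 6

    def test_degenerate_baseline_rejected(self, protocol):
        with pytest.raises(ValueError, match="degenerate"):
            is_significant(np.zeros(protocol.n_frames), protocol)

    def test_peak_searched_over_full_stimulus_window(self, protocol, rng):
        trace = self._trace_with_baseline_noise(protocol, 0.01, 0.0, rng)
        trace[protocol.offset_frame - 1] = 0.2  # last stimulus frame counts
        assert is_significant(trace, protocol)[0]
        trace[protocol.offset_frame - 1] = 0.0
        trace[protocol.offset_frame + 5] = 0.2  # post-stimulus peak does not
        assert not is_significant(trace, protocol)[0]


class TestAssignPreference:
    LABELS = ("water", "NaCl", "LCA")

    def test_largest_significant_response_wins(self):
        pref = assign_preference([0.1, 0.5, 0.2], [False, True, False], self.LABELS)
        assert pref == "NaCl"

    def test_no_significant_response_gives_none(self):
        assert assign_preference([0.1, 0.5, 0.2], [False] * 3, self.LABELS) is None

    def test_pure_suppression_not_classified(self):
        assert assign_preference([-0.5, -0.1, -0.2], [True, True, False], self.LABELS) is None

    def test_tie_goes_to_protocol_order_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            pref = assign_preference([0.5, 0.5, 0.1], [True, True, False], self.LABELS)
        assert pref == "water"

    def test_preference_can_differ_from_significance(self):
        # the largest signed response wins even if another stimulus was significant
        pref = assign_preference([0.6, 0.2, 0.1], [False, True, False], self.LABELS)
        assert pref == "water"


class TestLifetimeSparseness:
    def test_one_hot_is_one_over_m(self):
        assert lifetime_sparseness([1, 0, 0, 0, 0, 0, 0]) == pytest.approx(1 / 7, abs=1e-12)

    def test_uniform_is_one(self):
        assert lifetime_sparseness([0.3] * 7) == pytest.approx(1.0, abs=1e-12)

    def test_hand_derived_two_stimulus_case(self):
        r = [0.5, 0.25, 0, 0, 0, 0, 0]
        assert lifetime_sparseness(r) == pytest.approx(9 / 35, abs=1e-12)

    def test_negative_magnitudes_rectified(self):
        assert lifetime_sparseness([0.5, -0.25, 0, 0, 0, 0, 0]) == pytest.approx(1 / 7, abs=1e-12)

    def test_all_zero_is_nan(self):
        assert np.isnan(lifetime_sparseness([0.0, 0.0, -0.1]))

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1e-3, max_value=10.0)),
            min_size=2,
            max_size=12,
        ),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_scale_invariance_and_bounds(self, r, c):
        r = np.asarray(r)
        ls = lifetime_sparseness(r)
        if np.isnan(ls):
            assert not r.any()
            return
        assert 0 < ls <= 1 + 1e-12
        assert ls >= 1 / r.size - 1e-12
        assert lifetime_sparseness(c * r) == pytest.approx(ls, rel=1e-9)


def _make_table(protocol, magnitudes, prefs, ls=None, cell_ids=None):
    """Assemble a ResponseTable directly from magnitude rows (test helper)."""
    labels = list(protocol.stimulus_labels)
    cell_ids = cell_ids or [f"c{i:03d}" for i in range(len(magnitudes))]
    rows = []
    for cid, mags in zip(cell_ids, magnitudes):
        for stim, m in zip(labels, mags):
            rows.append(
                {"cell_id": cid, "stimulus": stim, "magnitude": m, "peak_z": np.nan,
                 "significant": True}
            )
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "preferred": prefs,
            "ls": ls if ls is not None else np.nan,
            "n_significant": 1,
        }
    )
    return ResponseTable(long=pd.DataFrame(rows), cells=cells, protocol=protocol)


class TestSortPopulationHeatmap:
    def test_within_group_descending_strength(self, protocol):
        mags = [[0.2, 0, 0, 0, 0, 0, 0], [0.5, 0, 0, 0, 0, 0, 0]]
        table = _make_table(protocol, mags, ["water", "water"])
        order, matrix = sort_population_heatmap(table)
        assert order == ["c001", "c000"]
        assert matrix[0, 0] == 0.5

    def test_groups_follow_protocol_stimulus_order(self, protocol):
        mags = [[0, 0.4, 0, 0, 0, 0, 0], [0.2, 0, 0, 0, 0, 0, 0]]
        table = _make_table(protocol, mags, ["NaCl", "water"])
        order, _ = sort_population_heatmap(table)
        assert order == ["c001", "c000"]  # water group precedes NaCl group

    def test_matches_brute_force_lexicographic_oracle(self, protocol, rng):
        labels = list(protocol.stimulus_labels)
        n = 40
        mags = rng.uniform(-0.2, 0.8, size=(n, len(labels)))
        prefs = [labels[j] for j in mags.argmax(axis=1)]
        table = _make_table(protocol, mags.tolist(), prefs)
        order, _ = sort_population_heatmap(table)
        # oracle: independent lexicographic sort on (pref_rank, -pref_mag, cell_id)
        keys = sorted(
            (labels.index(prefs[i]), -mags[i, labels.index(prefs[i])], f"c{i:03d}")
            for i in range(n)
        )
        assert order == [k[2] for k in keys]

    def test_unclassified_cells_excluded(self, protocol):
        mags = [[0.2, 0, 0, 0, 0, 0, 0], [0.5, 0, 0, 0, 0, 0, 0]]
        table = _make_table(protocol, mags, ["water", None])
        order, matrix = sort_population_heatmap(table)
        assert order == ["c000"]
        assert matrix.shape == (1, 7)


class TestCategoryCounts:
    def test_single_preparation_counts(self, protocol):
        mags = [[0.5, 0, 0, 0, 0, 0, 0]] * 3
        table = _make_table(protocol, mags, ["water"] * 3)
        cc = category_counts([table], groups=["surface"])
        water = cc.per_preparation.query("stimulus == 'water'")["count"].iloc[0]
        assert water == 3
        other = cc.per_preparation.query("stimulus != 'water'")["count"]
        assert (other == 0).all()

    def test_counts_sum_to_classified_total(self, protocol, rng):
        labels = list(protocol.stimulus_labels)
        tables, groups = [], []
        for p in range(4):
            n = int(rng.integers(5, 20))
            mags = rng.uniform(0, 1, size=(n, len(labels)))
            prefs = [labels[j] for j in mags.argmax(axis=1)]
            if n > 6:
                prefs[0] = None  # unclassified cell
            tables.append(_make_table(protocol, mags.tolist(), prefs))
            groups.append("surface" if p % 2 == 0 else "cave")
        cc = category_counts(tables, groups=groups)
        per = cc.per_preparation
        sums = per.groupby("preparation")["count"].sum()
        totals = per.drop_duplicates("preparation").set_index("preparation")["total"]
        pd.testing.assert_series_equal(sums, totals, check_names=False)

    def test_two_preparation_sem(self, protocol):
        t1 = _make_table(protocol, [[0.5, 0, 0, 0, 0, 0, 0]] * 4, ["water"] * 4)
        t2 = _make_table(protocol, [[0.5, 0, 0, 0, 0, 0, 0]] * 6, ["water"] * 6)
        cc = category_counts([t1, t2], groups=["cave", "cave"])
        row = cc.summary.query("stimulus == 'water'").iloc[0]
        assert row["mean_count"] == pytest.approx(5.0)
        assert row["sem_count"] == pytest.approx(1.0)

    def test_category_means_sum_to_mean_total(self, protocol, rng):
        """Linearity of the mean: per-category group means add up exactly to the
        group's mean number of classified neurons per preparation."""
        labels = list(protocol.stimulus_labels)
        tables = []
        for _ in range(5):
            n = int(rng.integers(10, 30))
            mags = rng.uniform(0, 1, size=(n, len(labels)))
            prefs = [labels[j] for j in mags.argmax(axis=1)]
            tables.append(_make_table(protocol, mags.tolist(), prefs))
        cc = category_counts(tables, groups=["surface"] * 5)
        mean_sum = cc.summary["mean_count"].sum()
        mean_total = cc.group_totals()["mean_total"].iloc[0]
        assert mean_sum == pytest.approx(mean_total, abs=1e-12)


class TestBuildResponseTable:
    def test_planted_response_detected_end_to_end(self, protocol, rng):
        labels = protocol.stimulus_labels
        n_frames = protocol.n_frames
        onset = protocol.onset_frame
        per_stim = {}
        for stim in labels:
            data = rng.normal(0, 0.005, size=(2, n_frames))
            if stim == "alanine":
                data[0, onset : onset + 50] += 0.6  # strong planted response, cell 0
            per_stim[stim] = TraceMatrix(
                data=data, cell_ids=["a", "b"], kind="dff_filtered",
                protocol=protocol, trial="mean",
            )
        table = build_response_table(per_stim, protocol)
        cells = table.cells.set_index("cell_id")
        assert cells.loc["a", "preferred"] == "alanine"
        assert pd.isna(cells.loc["b", "preferred"])
        row = table.long.query("cell_id == 'a' and stimulus == 'alanine'").iloc[0]
        assert row["significant"]
        assert row["magnitude"] == pytest.approx(0.6, abs=0.01)
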