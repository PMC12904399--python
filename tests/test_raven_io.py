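"""Selection-table I/O, segment labeling, negative mining, splitting."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirenet import raven_io
from sirenet.raven_io import (
    CallAnnotation,
    SelectionTable,
    SelectionTableFormatError,
    mine_negatives,
    read_selection_table,
    segment_and_label,
    split_manifest,
    write_selection_table,
)


def _table(path, rows, header="Selection\tBegin Time (s)\tEnd Time (s)"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadWrite:
    def test_annotations_sorted_on_read(self, tmp_path):
        p = _table(tmp_path / "t.txt", ["1\t1.00\t1.50", "2\t0.20\t0.60"])
        table = read_selection_table(p, recording_duration_s=5.0)
        assert [(a.begin_s, a.end_s) for a in table.annotations] == [
            (0.20, 0.60),
            (1.00, 1.50),
        ]

    def test_header_only_gives_empty_table(self, tmp_path):
        p = _table(tmp_path / "t.txt", [])
        assert len(read_selection_table(p, 10.0)) == 0

    def test_missing_column_names_it(self, tmp_path):
        p = _table(tmp_path / "t.txt", ["1\t1.0"], header="Selection\tBegin Time (s)")
        with pytest.raises(SelectionTableFormatError, match=r"End Time \(s\)"):
            read_selection_table(p, 10.0)

    def test_non_numeric_time_reports_row(self, tmp_path):
        p = _table(tmp_path / "t.txt", ["1\t0.5\t1.0", "2\toops\t2.0"])
        with pytest.raises(SelectionTableFormatError, match="row 2"):
            read_selection_table(p, 10.0)

    def test_end_before_begin_rejected(self, tmp_path):
        p = _table(tmp_path / "t.txt", ["1\t2.0\t1.0"])
        with pytest.raises(SelectionTableFormatError, match="end <= begin"):
            read_selection_table(p, 10.0)

    def test_annotation_past_duration_is_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            table = SelectionTable(
                "r", 2.0, (CallAnnotation("r", 1.5, 2.7),)
            )
        assert table.annotations[0].end_s == 2.0

    def test_five_row_round_trip(self, tmp_path, tiny_table):
        extra = tiny_table.annotations + (
            CallAnnotation("rec-a", 0.1, 0.35),
            CallAnnotation("rec-a", 2.0, 2.6, 2500.0, 7000.0),
            CallAnnotation("rec-a", 4.0, 4.8),
        )
        table = SelectionTable("rec-a", 5.0, extra)
        path = write_selection_table(table, tmp_path / "out.selections.txt")
        back = read_selection_table(path, 5.0, recording_id="rec-a")
        assert len(back) == 5
        for a, b in zip(table.annotations, back.annotations):
            assert a.begin_s == pytest.approx(b.begin_s, abs=1e-4)
            assert a.end_s == pytest.approx(b.end_s, abs=1e-4)

    def test_random_round_trip_within_1e4_seconds(self, tmp_path, rng):
        begins = np.sort(rng.uniform(0, 99, size=100))
        anns = tuple(
            CallAnnotation("r", float(b), float(b + rng.uniform(0.01, 0.5)))
            for b in begins
        )
        # space annotations out so none collide after sorting
        table = SelectionTable("r", 200.0, anns)
        path = write_selection_table(table, tmp_path / "r.txt")
        back = read_selection_table(path, 200.0)
        assert len(back) == len(table)
        for a, b in zip(table.annotations, back.annotations):
            assert abs(a.begin_s - b.begin_s) <= 1e-4
            assert abs(a.end_s - b.end_s) <= 1e-4

    def test_empty_table_writes_header_only(self, tmp_path):
        path = write_selection_table(
            SelectionTable("r", 1.0), tmp_path / "empty.txt"
        )
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and "Begin Time (s)" in lines[0]


class TestSegmentAndLabel:
    def test_overlap_enumeration(self):
        table = SelectionTable("r", 1.0, (CallAnnotation("r", 0.15, 0.45),))
        segs = segment_and_label(table)
        labels = {round(s.start_s, 1): s.label for s in segs}
        assert labels == {
            0.0: "positive",
            0.2: "positive",
            0.4: "positive",
            0.6: "negative",
            0.8: "negative",
        }

    def test_touching_endpoints_do_not_count(self):
        table = SelectionTable("r", 1.0, (CallAnnotation("r", 0.2, 0.4),))
        segs = segment_and_label(table)
        positives = [round(s.start_s, 1) for s in segs if s.label == "positive"]
        assert positives == [0.2]
        assert segs[1].overlap_fraction == pytest.approx(1.0)

    def test_no_annotations_all_negative(self):
        segs = segment_and_label(SelectionTable("r", 2.0))
        assert len(segs) == 10
        assert all(s.label == "negative" for s in segs)

    def test_segment_count_is_floor_duration_over_window(self):
        for dur in (1.0, 2.0, 0.95, 3.17):
            segs = segment_and_label(SelectionTable("r", dur))
            assert len(segs) == int(dur / 0.2 + 1e-9)

    def test_window_longer_than_recording_warns_empty(self):
        with pytest.warns(UserWarning, match="window"):
            assert segment_and_label(SelectionTable("r", 0.1)) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        begin=st.floats(0.0, 8.0),
        dur=st.floats(0.25, 1.5),
    )
    def test_every_annotation_yields_enough_positives(self, begin, dur):
        """A call of duration d covers at least ceil(d/w) - 1 full windows."""
        table = SelectionTable("r", 10.0, (CallAnnotation("r", begin, begin + dur),))
        segs = segment_and_label(table)
        n_pos = sum(s.label == "positive" for s in segs)
        assert n_pos >= int(np.ceil(dur / 0.2)) - 1
        assert n_pos >= 1


class TestMineNegatives:
    def test_gap_tiling_counts(self, tiny_table):
        negs = mine_negatives(tiny_table)
        assert len(negs) == 5 + 7 + 8

    def test_no_gap_no_negatives(self):
        table = SelectionTable("r", 1.0, (CallAnnotation("r", 0.0, 1.0),))
        assert mine_negatives(table) == []

    def test_guard_shrinks_gaps_per_tiling_oracle(self, tiny_table):
        guard = 0.1

        def oracle_count(g0, g1):
            usable = (g1 - guard) - (g0 + guard)
            return max(int(np.floor(usable / 0.2 + 1e-9)), 0)

        expected = sum(
            oracle_count(g0, g1) for g0, g1 in [(0, 1.0), (1.5, 3.0), (3.4, 5.0)]
        )
        assert len(mine_negatives(tiny_table, guard_s=guard)) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 19.0), min_size=0, max_size=6))
    def test_mined_negatives_never_overlap_annotations(self, starts):
        anns, last_end = [], 0.0
        for s in sorted(starts):
            if s < last_end:
                continue
            end = s + 0.4
            if end > 20.0:
                break
            anns.append(CallAnnotation("r", s, end))
            last_end = end
        table = SelectionTable("r", 20.0, tuple(anns))
        for seg in mine_negatives(table):
            for a in table.annotations:
                overlap = min(seg.end_s, a.end_s) - max(seg.start_s, a.begin_s)
                assert overlap <= 1e-9


class TestSplitManifest:
    def _rows(self, n, n_pos, rng):
        rows = []
        for i in range(n):
            pos = i < n_pos
            rows.append(
                raven_io.LabeledSegment(
                    "r", i * 0.2, 0.2,
                    "positive" if pos else "negative",
                    overlap_fraction=1.0 if pos else 0.0,
                )
            )
        return rows

    def test_exact_fraction(self, rng):
        m = split_manifest(self._rows(100, 20, rng), 0.8, seed=7)
        assert m.split.count("train") == 80
        assert m.split.count("val") == 20

    def test_deterministic_assignment(self, rng):
        rows = self._rows(50, 10, rng)
        assert split_manifest(rows, 0.8, 3).split == split_manifest(rows, 0.8, 3).split

    def test_prevalence_preserved_within_5_points(self, rng):
        rows = self._rows(1000, 300, rng)
        m = split_manifest(rows, 0.2, seed=11)
        counts = m.class_counts()
        assert counts["train"]["positive"] + counts["train"]["negative"] == 200
        for split in ("train", "val"):
            total = counts[split]["positive"] + counts[split]["negative"]
            prevalence = counts[split]["positive"] / total
            assert abs(prevalence - 0.3) < 0.05

    def test_fraction_bounds(self, rng):
        with pytest.raises(ValueError):
            split_manifest(self._rows(10, 5, rng), 1.0, 0)
        with pytest.raises(ValueError):
            split_manifest([], 0.5, 0)

    def test_manifest_csv_round_trip(self, tmp_path, rng):
        m = split_manifest(self._rows(30, 10, rng), 0.8, seed=2)
        path = raven_io.write_manifest(m, tmp_path / "m.csv")
        back = raven_io.read_manifest(path)
        assert back.split == m.split
        for a, b in zip(m.rows, back.rows):
            assert a.label == b.label
            assert a.start_s == pytest.approx(b.start_s, abs=1e-4)
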