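from __future__ import annotations

from datetime import datetime, time, timedelta

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from PIL import Image

from mielapse.sequence_io import (
    Annotation,
    BoundingBox,
    Detection,
    TimeLapseSequence,
    expected_frame_count,
    load_sequence,
    read_detections_csv,
    read_yolo_annotations,
    segment_runs,
    write_detections_csv,
    write_yolo_annotations,
    yolo_to_box,
)

from conftest import T0, make_frame


def _write_image(path, value=100, size=(8, 6)):
    arr = np.full((size[1], size[0], 3), value, dtype=np.uint8)
    Image.fromarray(arr).save(path)


class TestLoadSequence:
    def test_frames_sorted_by_timestamp(self, tmp_path):
        for stem in ["20220601-100100", "20220601-100000", "20220601-100030"]:
            _write_image(tmp_path / f"{stem}.png")
        seq = load_sequence(tmp_path)
        assert seq.frame_ids == ["20220601-100000", "20220601-100030", "20220601-100100"]
        assert seq.skipped_files == []

    def test_ordering_follows_timestamp_not_lexical_name(self, tmp_path):
        # day-first naming: lexical and chronological order disagree
        _write_image(tmp_path / "01-07-2022_100000.png", value=1)
        _write_image(tmp_path / "30-06-2022_100000.png", value=2)
        seq = load_sequence(tmp_path, timestamp_pattern="%d-%m-%Y_%H%M%S")
        assert [f.timestamp for f in seq] == [
            datetime(2022, 6, 30, 10), datetime(2022, 7, 1, 10)]

    def test_corrupt_file_skipped_with_count(self, tmp_path):
        _write_image(tmp_path / "20220601-100000.png")
        (tmp_path / "20220601-100030.png").write_bytes(b"not an image at all")
        seq = load_sequence(tmp_path)
        assert len(seq) == 1
        assert seq.skipped_files == ["20220601-100030.png"]

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_sequence(tmp_path)

    def test_duplicate_timestamps_error_names_files(self, tmp_path):
        _write_image(tmp_path / "20220601-100000.png")
        _write_image(tmp_path / "20220601-100000.jpg")
        with pytest.raises(ValueError, match="20220601-100000"):
            load_sequence(tmp_path)


class TestSegmentRuns:
    def _seq(self, offsets_s):
        frames = [make_frame(np.zeros((4, 4, 3)), 0)]
        t = 0.0
        for gap in offsets_s:
            t += gap
            frames.append(make_frame(np.zeros((4, 4, 3)), t / 30.0))
        return TimeLapseSequence(frames)

    def test_uniform_gaps_single_run(self):
        seq = self._seq([30, 30, 30])
        assert [len(r) for r in segment_runs(seq, 45)] == [4]

    def test_overnight_gap_splits(self):
        seq = self._seq([30, 6 * 3600, 30])
        assert [len(r) for r in segment_runs(seq, 45)] == [2, 2]

    def test_mixed_gaps_enumerated_by_hand(self):
        # gaps (30, 30, 90, 30) with max_gap 60 -> runs of sizes (3, 2)
        seq = self._seq([30, 30, 90, 30])
        assert [len(r) for r in segment_runs(seq, 60)] == [3, 2]

    def test_max_gap_below_interval_rejected(self):
        seq = self._seq([30])
        with pytest.raises(ValueError):
            segment_runs(seq, 10)

    @given(gaps=st.lists(st.sampled_from([30.0, 40.0, 90.0, 7200.0]), max_size=12),
           max_gap=st.sampled_from([45.0, 60.0, 100.0]))
    def test_partition_properties(self, gaps, max_gap):
        seq = self._seq(gaps)
        runs = segment_runs(seq, max_gap)
        # concatenation preserves order and length
        assert [f.frame_id for r in runs for f in r] == seq.frame_ids
        for r in runs:
            for a, b in zip(r.frames, r.frames[1:]):
                assert (b.timestamp - a.timestamp).total_seconds() <= max_gap
        for r1, r2 in zip(runs, runs[1:]):
            gap = (r2.frames[0].timestamp - r1.frames[-1].timestamp).total_seconds()
            assert gap > max_gap


class TestExpectedFrameCount:
    def test_full_recording_day(self):
        assert expected_frame_count(time(4, 30), time(22, 30), 30) == 2160

    def test_zero_length_window(self):
        assert expected_frame_count("10:00", "10:00", 30) == 0

    def test_one_hour_at_minute_interval(self):
        assert expected_frame_count("10:00", "11:00", 60) == 60

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError):
            expected_frame_count("10:00", "11:00", 0)

    def test_matches_tick_enumeration(self, rng):
        for _ in range(100):
            s = int(rng.integers(0, 80000))
            e = int(rng.integers(s, 86400))
            interval = int(rng.integers(1, 600))
            start = time(s // 3600, (s // 60) % 60, s % 60)
            end = time(e // 3600, (e // 60) % 60, e % 60)
            ticks = len(range(s, e, interval))  # capture instants in [s, e)
            assert expected_frame_count(start, end, interval) == ticks


class TestYoloFormat:
    def test_centered_box(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("0 0.5 0.5 0.5 0.5\n")
        (ann,) = read_yolo_annotations(f, 100, 100)
        assert (ann.box.xmin, ann.box.ymin, ann.box.xmax, ann.box.ymax) == (25, 25, 75, 75)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("")
        assert read_yolo_annotations(f, 100, 100) == []

    def test_full_hd_corner_rounding(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("0 0.25 0.10 0.10 0.04\n")
        (ann,) = read_yolo_annotations(f, 1920, 1080)
        assert (ann.box.xmin, ann.box.ymin, ann.box.xmax, ann.box.ymax) == (384, 86, 576, 130)

    def test_malformed_line_reports_line_number(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("0 0.5 0.5 0.5 0.5\n0 0.5 0.5\n")
        with pytest.raises(ValueError, match=":2"):
            read_yolo_annotations(f, 100, 100)

    def test_out_of_range_value_rejected(self, tmp_path):
        f = tmp_path / "a.txt"
        f.write_text("0 1.5 0.5 0.5 0.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_yolo_annotations(f, 100, 100)

    def test_exact_roundtrip(self, tmp_path):
        ann = Annotation("a", BoundingBox(25, 25, 75, 75))
        f = tmp_path / "a.txt"
        write_yolo_annotations([ann], 100, 100, f)
        (back,) = read_yolo_annotations(f, 100, 100)
        assert back.box == ann.box

    def test_empty_roundtrip(self, tmp_path):
        f = tmp_path / "a.txt"
        write_yolo_annotations([], 100, 100, f)
        assert f.read_text() == ""
        assert read_yolo_annotations(f, 100, 100) == []

    def test_out_of_bounds_box_rejected_on_write(self, tmp_path):
        with pytest.raises(ValueError, match="outside"):
            write_yolo_annotations(
                [Annotation("a", BoundingBox(90, 0, 120, 10))], 100, 100, tmp_path / "a.txt")

    def test_random_boxes_roundtrip_within_one_pixel(self, tmp_path, rng):
        w, h = 1920, 1080
        boxes = []
        for _ in range(100):
            x0 = int(rng.integers(0, w - 2))
            y0 = int(rng.integers(0, h - 2))
            x1 = int(rng.integers(x0 + 1, w))
            y1 = int(rng.integers(y0 + 1, h))
            boxes.append(BoundingBox(x0, y0, x1, y1))
        f = tmp_path / "a.txt"
        write_yolo_annotations([Annotation("a", b) for b in boxes], w, h, f)
        back = read_yolo_annotations(f, w, h)
        for orig, rt in zip(boxes, back):
            for edge in ("xmin", "ymin", "xmax", "ymax"):
                assert abs(getattr(rt.box, edge) - getattr(orig, edge)) <= 1

    def test_tiny_box_survives_quantization(self):
        box = yolo_to_box(0.5, 0.5, 0.001, 0.001, 100, 100)
        assert box.area >= 1


class TestDetectionsCsv:
    def _random_detections(self, rng, n=50):
        dets = []
        for i in range(n):
            x0 = float(rng.integers(0, 400))
            y0 = float(rng.integers(0, 200))
            dets.append(Detection(
                frame_id=f"frame{i % 7}",
                box=BoundingBox(x0, y0, x0 + float(rng.integers(1, 40)),
                                y0 + float(rng.integers(1, 40))),
                confidence=float(rng.uniform()),
                class_id=0,
            ))
        return dets

    def test_single_row(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("frame_id,xmin,ymin,xmax,ymax,confidence,class_id\n"
                     "a,1,2,3,4,0.5,0\n")
        (det,) = read_detections_csv(f)
        assert det.frame_id == "a"
        assert (det.box.xmin, det.box.ymin, det.box.xmax, det.box.ymax) == (1, 2, 3, 4)
        assert det.confidence == 0.5

    def test_roundtrip_50(self, tmp_path, rng):
        dets = self._random_detections(rng)
        f = tmp_path / "d.csv"
        write_detections_csv(dets, f)
        back = read_detections_csv(f)
        assert back == dets

    def test_roundtrip_with_timestamps(self, tmp_path):
        dets = [Detection("a", BoundingBox(0, 0, 5, 5), 0.9,
                          timestamp=T0 + timedelta(seconds=30), camera_id="S1-0")]
        f = tmp_path / "d.csv"
        write_detections_csv(dets, f)
        assert read_detections_csv(f) == dets

    def test_confidence_out_of_range_reports_row(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("frame_id,xmin,ymin,xmax,ymax,confidence,class_id\n"
                     "a,1,2,3,4,0.5,0\n"
                     "b,1,2,3,4,1.5,0\n")
        with pytest.raises(ValueError, match="row 3"):
            read_detections_csv(f)

    def test_missing_column_named(self, tmp_path):
        f = tmp_path / "d.csv"
        f.write_text("frame_id,xmin,ymin,xmax,ymax,class_id\na,1,2,3,4,0\n")
        with pytest.raises(ValueError, match="confidence"):
            read_detections_csv(f)


class TestInvariants:
    def test_timestamps_must_strictly_increase(self):
        frames = [make_frame(np.zeros((4, 4, 3)), 0), make_frame(np.zeros((4, 4, 3)), 0)]
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeLapseSequence(frames)

    def test_mixed_shapes_rejected(self):
        frames = [make_frame(np.zeros((4, 4, 3)), 0), make_frame(np.zeros((5, 4, 3)), 1)]
        with pytest.raises(ValueError, match="mixed shapes"):
            TimeLapseSequence(frames)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(5, 5, 5, 10)
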