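"""Annotation I/O round-trips, splitting arithmetic and dataset statistics."""

import numpy as np
import pytest

from ktyolo.datasets_io import (
    CLASS_NAMES,
    AnnotatedImage,
    box_to_yolo_line,
    class_counts,
    frame_indices,
    read_cvat_xml,
    read_detections_file,
    read_yolo_txt,
    split_dataset,
    write_detections_file,
    write_yolo_txt,
    yolo_line_to_box,
)
from ktyolo.evalmetrics import DetectionRecord

CVAT_FIXTURE = """<?xml version="1.0" encoding="utf-8"?>
<annotations>
  <version>1.1</version>
  <image id="0" name="pen1_day_summer.png" width="200" height="150">
    <box label="standing" xtl="10.0" ytl="20.0" xbr="50.0" ybr="90.0"/>
    <box label="lying" xtl="60.5" ytl="100.25" xbr="120.0" ybr="130.0"/>
    <box label="drinking" xtl="180.0" ytl="40.0" xbr="199.0" ybr="80.0"/>
  </image>
  <image id="1" name="pen1_night_winter.png" width="200" height="150">
    <box label="eating" xtl="5.0" ytl="0.0" xbr="45.0" ybr="30.0"/>
  </image>
  <image id="2" name="pen2.png" width="100" height="100"/>
</annotations>
"""


@pytest.fixture
def cvat_file(tmp_path):
    p = tmp_path / "annotations.xml"
    p.write_text(CVAT_FIXTURE)
    return p


class TestCvat:
    def test_fixture_parses_with_authored_counts(self, cvat_file):
        images = read_cvat_xml(cvat_file)
        assert len(images) == 3
        assert [len(im.records) for im in images] == [3, 1, 0]
        first = images[0]
        assert first.capture_tag == "day" and first.season_tag == "summer"
        assert first.records[0].class_id == 0
        assert first.records[1].box == (60.5, 100.25, 120.0, 130.0)
        assert images[1].capture_tag == "night"
        assert images[2].capture_tag == "unknown"

    def test_unknown_label_raises(self, tmp_path):
        bad = CVAT_FIXTURE.replace('label="eating"', 'label="flying"')
        p = tmp_path / "bad.xml"
        p.write_text(bad)
        with pytest.raises(ValueError, match="flying"):
            read_cvat_xml(p)

    def test_out_of_bounds_box_raises(self, tmp_path):
        bad = CVAT_FIXTURE.replace('xbr="199.0"', 'xbr="210.0"')
        p = tmp_path / "oob.xml"
        p.write_text(bad)
        with pytest.raises(ValueError, match="pen1_day_summer"):
            read_cvat_xml(p)


class TestYoloTxt:
    def test_documented_conversion(self):
        cx, cy, w, h = box_to_yolo_line((10, 20, 50, 60), 100, 100)
        assert (cx, cy, w, h) == pytest.approx((0.30, 0.40, 0.40, 0.40))
        assert yolo_line_to_box(cx, cy, w, h, 100, 100) == pytest.approx((10, 20, 50, 60))

    def test_roundtrip_of_random_boxes(self, tmp_path):
        rng = np.random.default_rng(0)
        records = []
        for i in range(50):
            x1, y1 = rng.uniform(0, 500, 2)
            w, h = rng.uniform(5, 100, 2)
            records.append(DetectionRecord("im_day_winter", int(rng.integers(0, 4)),
                                           (x1, y1, min(x1 + w, 640), min(y1 + h, 640))))
        im = AnnotatedImage("im_day_winter", 640, 640, records)
        write_yolo_txt([im], tmp_path)
        back = read_yolo_txt(tmp_path, {"im_day_winter": (640, 640)})
        assert len(back[0].records) == 50
        for a, b in zip(records, back[0].records):
            assert a.class_id == b.class_id
            assert np.max(np.abs(np.array(a.box) - np.array(b.box))) <= 1e-3  # 6-decimal text
        assert (tmp_path / "classes.txt").read_text().split() == list(CLASS_NAMES)

    def test_zero_width_entry_rejected(self):
        with pytest.raises(ValueError):
            yolo_line_to_box(0.5, 0.5, 0.0, 0.1, 100, 100)
        with pytest.raises(ValueError):
            yolo_line_to_box(0.5, 1.2, 0.1, 0.1, 100, 100)


class TestDetectionsFile:
    def test_roundtrip_preserves_records(self, tmp_path):
        dets = [
            DetectionRecord("imgA", 0, (1.5, 2.25, 40.0, 50.0), 0.875),
            DetectionRecord("imgB", 3, (0.0, 0.0, 10.0, 12.0), 0.01),
        ]
        p = tmp_path / "dets.txt"
        write_detections_file(dets, p)
        back = read_detections_file(p)
        assert len(back) == 2
        for a, b in zip(dets, back):
            assert (a.image_id, a.class_id) == (b.image_id, b.class_id)
            assert a.score == pytest.approx(b.score, abs=1e-6)
            assert a.box == pytest.approx(b.box, abs=1e-2)

    def test_ground_truth_without_score_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_detections_file([DetectionRecord("a", 0, (0, 0, 5, 5))], tmp_path / "x.txt")

    def test_malformed_line_reports_position(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("imgA 0 0.5 1 2 3\n")
        with pytest.raises(ValueError, match="line 1"):
            read_detections_file(p)


class TestSplit:
    def test_280_images_split_210_70(self):
        ids = [f"im{i:03d}" for i in range(280)]
        m = split_dataset(ids, 0.75, seed=0)
        assert len(m.train_ids) == 210 and len(m.test_ids) == 70
        assert set(m.train_ids) | set(m.test_ids) == set(ids)
        assert not set(m.train_ids) & set(m.test_ids)

    def test_same_seed_reproduces_manifest(self):
        ids = [f"im{i}" for i in range(37)]
        a = split_dataset(ids, 0.6, seed=5)
        b = split_dataset(ids, 0.6, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids
        c = split_dataset(ids, 0.6, seed=6)
        assert c.train_ids != a.train_ids

    def test_round_half_up_on_odd_sizes(self):
        m = split_dataset([f"i{k}" for k in range(7)], 0.5, seed=1)
        assert (len(m.train_ids), len(m.test_ids)) == (4, 3)

    def test_stratified_split_balances_tags(self):
        images = [AnnotatedImage(f"a{i}_day", 10, 10, [], "day", "unknown") for i in range(8)]
        images += [AnnotatedImage(f"b{i}_night", 10, 10, [], "night", "unknown") for i in range(8)]
        m = split_dataset(images, 0.75, seed=2, stratify_by="capture_tag")
        train_day = sum("day" in t for t in m.train_ids)
        train_night = sum("night" in t for t in m.train_ids)
        assert train_day == 6 and train_night == 6

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["only"], 0.5, seed=0)


class TestFrameSampling:
    @pytest.mark.parametrize(
        "n, interval, expected",
        [
            (900, 180, [0, 180, 360, 540, 720]),
            (100, 180, [0]),
            (5, 1, [0, 1, 2, 3, 4]),
        ],
    )
    def test_interval_sampling(self, n, interval, expected):
        assert frame_indices(n, interval) == expected

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ValueError):
            frame_indices(0, 180)
        with pytest.raises(ValueError):
            frame_indices(10, 0)


class TestClassCounts:
    def test_counts_and_totals(self, cvat_file):
        images = read_cvat_xml(cvat_file)
        m = split_dataset(images, 0.67, seed=0)
        df = class_counts(images, m)
        assert df.loc["total", "train"] + df.loc["total", "test"] == 4
        assert (df.loc["total"] == df.drop(index="total").sum()).all()

    def test_missing_image_raises(self, cvat_file):
        images = read_cvat_xml(cvat_file)
        m = split_dataset(images, 0.67, seed=0)
        with pytest.raises(ValueError):
            class_counts(images[:1], m)
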