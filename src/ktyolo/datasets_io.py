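"""Annotation I/O, deterministic splitting, frame sampling and dataset stats.

Two annotation dialects are supported: CVAT-for-images 1.1 XML (corner
coordinates ``xtl/ytl/xbr/ybr``) and YOLO-txt (one file per image, lines of
``class cx cy w h`` normalized to [0, 1]).  The behavior vocabulary is fixed:
0 standing, 1 lying, 2 eating, 3 drinking.  Day/night and season tags are
carried as image metadata, parsed from the ``<id>_<day|night>_<summer|winter>``
filename convention when present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .evalmetrics import DetectionRecord

__all__ = [
    "CLASS_NAMES",
    "CLASS_IDS",
    "AnnotatedImage",
    "SplitManifest",
    "read_cvat_xml",
    "read_yolo_txt",
    "write_yolo_txt",
    "read_detections_file",
    "write_detections_file",
    "yolo_line_to_box",
    "box_to_yolo_line",
    "split_dataset",
    "frame_indices",
    "class_counts",
    "parse_tags",
]

CLASS_NAMES = ("standing", "lying", "eating", "drinking")
CLASS_IDS = {name: i for i, name in enumerate(CLASS_NAMES)}


@dataclass
class AnnotatedImage:
    image_id: str
    width: int
    height: int
    records: list = field(default_factory=list)  # ground-truth DetectionRecords
    capture_tag: str = "unknown"  # day | night | unknown
    season_tag: str = "unknown"  # summer | winter | unknown

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        for r in self.records:
            self._check_record(r)

    def _check_record(self, r: DetectionRecord) -> None:
        x1, y1, x2, y2 = r.box
        if x1 < 0 or y1 < 0 or x2 > self.width or y2 > self.height:
            raise ValueError(
                f"box {r.box} outside bounds of image {self.image_id!r} "
                f"({self.width}x{self.height})"
            )
        if r.class_id not in range(len(CLASS_NAMES)):
            raise ValueError(f"unknown class_id {r.class_id} in image {self.image_id!r}")


@dataclass
class SplitManifest:
    train_ids: list
    test_ids: list
    ratio: float
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": list(self.train_ids),
                    "test": list(self.test_ids),
                    "ratio": self.ratio,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "SplitManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["train"], d["test"], d["ratio"], d["seed"])


def parse_tags(image_id: str):
    """Extract (capture_tag, season_tag) from an ``id_day_summer``-style name."""
    parts = Path(image_id).stem.split("_")
    capture = next((p for p in parts if p in ("day", "night")), "unknown")
    season = next((p for p in parts if p in ("summer", "winter")), "unknown")
    return capture, season


def read_cvat_xml(path) -> list:
    """Parse a CVAT-for-images 1.1 export into AnnotatedImages.

    Unknown labels and out-of-bounds boxes raise with the offending image
    named; empty ``<image>`` elements yield zero-record entries.
    """
    tree = etree.parse(str(path))
    images = []
    unknown: list = []
    for el in tree.getroot().iter("image"):
        image_id = el.get("name")
        width, height = int(el.get("width")), int(el.get("height"))
        records = []
        for box in el.iter("box"):
            label = box.get("label")
            if label not in CLASS_IDS:
                unknown.append((image_id, label))
                continue
            records.append(
                DetectionRecord(
                    image_id=image_id,
                    class_id=CLASS_IDS[label],
                    box=(
                        float(box.get("xtl")),
                        float(box.get("ytl")),
                        float(box.get("xbr")),
                        float(box.get("ybr")),
                    ),
                )
            )
        capture, season = parse_tags(image_id)
        images.append(
            AnnotatedImage(image_id, width, height, records, capture, season)
        )
    if unknown:
        raise ValueError(f"unknown labels (image, label): {unknown}")
    return images


def yolo_line_to_box(cx: float, cy: float, w: float, h: float, width: int, height: int):
    """Normalized center format -> pixel corner format (exact arithmetic)."""
    for v in (cx, cy, w, h):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"YOLO coordinate {v} outside [0, 1]")
    if w <= 0 or h <= 0:
        raise ValueError("YOLO box width/height must be positive")
    return (
        (cx - w / 2) * width,
        (cy - h / 2) * height,
        (cx + w / 2) * width,
        (cy + h / 2) * height,
    )


def box_to_yolo_line(box, width: int, height: int):
    """Pixel corner format -> normalized (cx, cy, w, h)."""
    x1, y1, x2, y2 = box
    return (
        (x1 + x2) / 2 / width,
        (y1 + y2) / 2 / height,
        (x2 - x1) / width,
        (y2 - y1) / height,
    )


def write_yolo_txt(images, label_dir) -> None:
    """One ``<id>.txt`` per image plus a ``classes.txt`` vocabulary file."""
    label_dir = Path(label_dir)
    label_dir.mkdir(parents=True, exist_ok=True)
    (label_dir / "classes.txt").write_text("\n".join(CLASS_NAMES) + "\n")
    for im in images:
        lines = []
        for r in im.records:
            cx, cy, w, h = box_to_yolo_line(r.box, im.width, im.height)
            lines.append(f"{r.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
        (label_dir / f"{Path(im.image_id).stem}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else "")
        )


def read_yolo_txt(label_dir, image_sizes) -> list:
    """Read YOLO-txt labels; ``image_sizes`` maps image_id -> (width, height)."""
    label_dir = Path(label_dir)
    images = []
    for image_id, (width, height) in sorted(image_sizes.items()):
        path = label_dir / f"{Path(image_id).stem}.txt"
        records = []
        if path.exists():
            for line in path.read_text().splitlines():
                if not line.strip():
                    continue
                cls, cx, cy, w, h = line.split()
                box = yolo_line_to_box(float(cx), float(cy), float(w), float(h), width, height)
                records.append(DetectionRecord(image_id, int(cls), box))
        capture, season = parse_tags(image_id)
        images.append(AnnotatedImage(image_id, width, height, records, capture, season))
    return images


def write_detections_file(dets, path) -> None:
    """One scored detection per line: ``image_id class score x1 y1 x2 y2``."""
    lines = []
    for d in dets:
        if d.score is None:
            raise ValueError(f"detection for {d.image_id!r} has no score")
        x1, y1, x2, y2 = d.box
        lines.append(f"{d.image_id} {d.class_id} {d.score:.6f} "
                     f"{x1:.2f} {y1:.2f} {x2:.2f} {y2:.2f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections_file(path) -> list:
    """Inverse of :func:`write_detections_file`."""
    dets = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"line {ln}: expected 7 fields, got {len(parts)}")
        image_id, cls, score, x1, y1, x2, y2 = parts
        dets.append(DetectionRecord(image_id, int(cls),
                                    (float(x1), float(y1), float(x2), float(y2)),
                                    float(score)))
    return dets


def split_dataset(images, ratio: float, seed: int, stratify_by: str | None = None) -> SplitManifest:
    """Deterministic image-level train/test split.

    Train count is ``round(ratio * N)`` with round-half-up.  With
    ``stratify_by="capture_tag"`` the split ratio is applied within each tag
    group so day/night are balanced across splits.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    ids = [im.image_id if isinstance(im, AnnotatedImage) else str(im) for im in images]
    if len(ids) < 2:
        raise ValueError("need at least 2 images to split")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate image ids")
    rng = np.random.default_rng(seed)

    def _take(group):
        group = sorted(group)
        n_train = int(math.floor(ratio * len(group) + 0.5))  # round half up
        perm = rng.permutation(len(group))
        train = [group[i] for i in perm[:n_train]]
        test = [group[i] for i in perm[n_train:]]
        return train, test

    if stratify_by is None:
        train, test = _take(ids)
    else:
        by_tag: dict = {}
        for im in images:
            tag = getattr(im, stratify_by, "unknown") if isinstance(im, AnnotatedImage) else "unknown"
            by_tag.setdefault(tag, []).append(
                im.image_id if isinstance(im, AnnotatedImage) else str(im)
            )
        train, test = [], []
        for tag in sorted(by_tag):
            tr, te = _take(by_tag[tag])
            train += tr
            test += te
    return SplitManifest(train, test, ratio, seed)


def frame_indices(n_frames: int, interval: int) -> list:
    """Indices sampled at a fixed frame interval: 0, interval, 2*interval, ..."""
    if n_frames < 1 or interval < 1:
        raise ValueError("n_frames and interval must be positive")
    return list(range(0, n_frames, interval))


def class_counts(images, manifest: SplitManifest) -> pd.DataFrame:
    """Per-class instance counts by split, with a totals row."""
    by_id = {im.image_id: im for im in images}
    missing = [i for i in list(manifest.train_ids) + list(manifest.test_ids) if i not in by_id]
    if missing:
        raise ValueError(f"manifest ids missing from collection: {missing[:5]}")
    counts = {"train": [0] * len(CLASS_NAMES), "test": [0] * len(CLASS_NAMES)}
    for split, split_ids in (("train", manifest.train_ids), ("test", manifest.test_ids)):
        for image_id in split_ids:
            for r in by_id[image_id].records:
                counts[split][r.class_id] += 1
    df = pd.DataFrame(counts, index=list(CLASS_NAMES))
    df.loc["total"] = df.sum()
    return df
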