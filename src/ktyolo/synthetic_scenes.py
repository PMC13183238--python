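"""Synthetic dense-flock scene generator.

Renders pen images with ellipsoidal sheep proxies and exact bounding-box
ground truth, emulating the statistical structure of a dense sheep-barn
dataset: up to 36 instances per image, four behavior classes with heavy
imbalance (standing/lying/eating/drinking at roughly 50/16/32/2 percent of
instances), mutual occlusion controlled by a pairwise-IoU cap, and a
day/night illumination factor.  Class identity is encoded in geometry and
context rather than texture: standing sheep are tall bright ellipses, lying
sheep are flat wide ellipses with reduced contrast against the floor,
eating sheep abut the feed-trough strip along the top edge, and drinking
sheep abut a water-dispenser patch on the left or right edge.  Night mode
applies a global gain reduction and contrast compression; drinking
instances are never generated at night by default, mirroring the circadian
pattern of water intake.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .datasets_io import (
    CLASS_NAMES,
    AnnotatedImage,
    SplitManifest,
    write_yolo_txt,
)
from .evalmetrics import DetectionRecord, iou_matrix

__all__ = [
    "REFERENCE_TRAIN_COUNTS",
    "default_class_probs",
    "SceneSpec",
    "SyntheticScene",
    "PlacementError",
    "generate_scene",
    "generate_scenes",
    "generate_dataset",
]

# observed training-set instance counts per behavior
# (standing, lying, eating, drinking) in the emulated barn dataset
REFERENCE_TRAIN_COUNTS = (2725, 859, 1706, 125)
MAX_DENSITY = 36


def default_class_probs() -> np.ndarray:
    c = np.asarray(REFERENCE_TRAIN_COUNTS, dtype=np.float64)
    return c / c.sum()


class PlacementError(RuntimeError):
    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could not place {requested} instances under the occlusion cap "
            f"(achieved {achieved})"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass
class SceneSpec:
    width: int = 640
    height: int = 640
    n_instances: int = 12
    class_probs: tuple = field(default_factory=lambda: tuple(default_class_probs()))
    illumination: str = "day"  # day | night
    season: str = "winter"  # winter | summer (summer floor lowers lying contrast)
    occlusion_level: float = 0.3  # max allowed pairwise box IoU
    seed: int = 0
    max_density: int = MAX_DENSITY

    def __post_init__(self):
        p = np.asarray(self.class_probs, dtype=np.float64)
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_probs must be 4 nonnegative values summing to 1")
        if not 1 <= self.n_instances <= self.max_density:
            raise ValueError(
                f"n_instances must lie in [1, {self.max_density}], got {self.n_instances}"
            )
        if self.illumination not in ("day", "night"):
            raise ValueError("illumination must be 'day' or 'night'")
        if self.season not in ("winter", "summer"):
            raise ValueError("season must be 'winter' or 'summer'")
        if not 0.0 <= self.occlusion_level <= 1.0:
            raise ValueError("occlusion_level must lie in [0, 1]")


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    annotations: list  # DetectionRecords
    spec: SceneSpec


def _ellipse(img, cx, cy, a, b, color, soft=1.5):
    """Paint a filled ellipse with a soft edge onto ``img`` in place."""
    h, w = img.shape[:2]
    x0, x1 = max(0, int(cx - a - 2)), min(w, int(cx + a + 3))
    y0, y1 = max(0, int(cy - b - 2)), min(h, int(cy + b + 3))
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2
    alpha = np.clip((1.0 - d) * soft * max(a, b) / 2.0, 0.0, 1.0)[..., None]
    img[y0:y1, x0:x1] = (1 - alpha) * img[y0:y1, x0:x1] + alpha * np.asarray(color, dtype=np.float64)


def _instance_geometry(cls: int, base: float, rng, width: int, height: int,
                       trough_h: float, patch_w: float):
    """Sample (cx, cy, a, b, head) for one instance of a class."""
    if cls == 0:  # standing: tall ellipse anywhere on the floor
        a = base * rng.uniform(0.45, 0.60)
        b = base * rng.uniform(0.75, 0.95)
        cx = rng.uniform(a + 2, width - a - 2)
        cy = rng.uniform(trough_h + b + 2, height - b - 2)
    elif cls == 1:  # lying: flat wide ellipse
        a = base * rng.uniform(0.75, 0.95)
        b = base * rng.uniform(0.35, 0.48)
        cx = rng.uniform(a + 2, width - a - 2)
        cy = rng.uniform(trough_h + b + 2, height - b - 2)
    elif cls == 2:  # eating: tall ellipse abutting the trough strip at the top
        a = base * rng.uniform(0.45, 0.60)
        b = base * rng.uniform(0.75, 0.95)
        cx = rng.uniform(a + 2, width - a - 2)
        cy = trough_h + b * rng.uniform(0.15, 0.45)
    else:  # drinking: ellipse abutting a left/right dispenser patch
        a = base * rng.uniform(0.45, 0.60)
        b = base * rng.uniform(0.70, 0.90)
        side = rng.integers(0, 2)
        cx = patch_w + a * rng.uniform(0.1, 0.5) if side == 0 else width - patch_w - a * rng.uniform(0.1, 0.5)
        cy = rng.uniform(trough_h + b + 2, height - b - 2)
    return cx, cy, a, b


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene; bit-identical for identical specs.

    Raises :class:`PlacementError` when the occlusion cap cannot accommodate
    the requested instance count within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    trough_h = 0.09 * h
    patch_w = 0.05 * w

    floor_level = 95.0 if spec.season == "winter" else 135.0
    img = np.full((h, w, 3), floor_level, dtype=np.float64)
    img += rng.normal(0, 6.0, size=(h, w, 1))  # floor texture
    img += rng.normal(0, 3.0, size=(h, w, 3))
    # feed trough strip along the top edge
    img[: int(trough_h)] = 0.55 * img[: int(trough_h)] + np.array([28.0, 22.0, 12.0])
    # water dispenser patches on left and right edges
    for sl in (np.s_[:, : int(patch_w)], np.s_[:, w - int(patch_w) :]):
        img[sl] = 0.6 * img[sl] + np.array([18.0, 30.0, 55.0])

    # denser pens are filmed wider: proxy size shrinks with instance count so
    # the density ceiling of 36 remains placeable under the occlusion cap
    base = 0.11 * min(h, w) * float(np.clip(np.sqrt(12.0 / spec.n_instances), 0.55, 1.15))
    classes = rng.choice(4, size=spec.n_instances, p=np.asarray(spec.class_probs))
    placed_boxes: list = []
    placed: list = []
    max_attempts = 400
    for cls in classes:
        ok = False
        for _ in range(max_attempts):
            cx, cy, a, b = _instance_geometry(
                int(cls), base * rng.uniform(0.85, 1.15), rng, w, h, trough_h, patch_w
            )
            box = (
                max(0.0, cx - a), max(0.0, cy - b),
                min(float(w), cx + a), min(float(h), cy + b),
            )
            if box[2] - box[0] < 4 or box[3] - box[1] < 4:
                continue
            if placed_boxes:
                ious = iou_matrix(np.array([box]), np.array(placed_boxes))[0]
                if ious.max() > spec.occlusion_level:
                    continue
            placed_boxes.append(box)
            placed.append((int(cls), cx, cy, a, b, box))
            ok = True
            break
        if not ok:
            raise PlacementError(spec.n_instances, len(placed))

    # painter's order: back (small y) to front so overlaps look like occlusion
    annotations = []
    for idx, (cls, cx, cy, a, b, box) in enumerate(sorted(placed, key=lambda t: t[2])):
        fleece = rng.uniform(200, 235)
        if cls == 1:
            # lying blends toward the floor; summer floor is bright, so the
            # contrast gap narrows further (the seasonal failure mode)
            blend = 0.55 if spec.season == "summer" else 0.35
            fleece = (1 - blend) * fleece + blend * floor_level
        color = (fleece + rng.normal(0, 4), fleece + rng.normal(0, 4), fleece - rng.uniform(0, 12))
        _ellipse(img, cx, cy, a, b, color)
        # head dot toward the behavior's focus of attention
        hr = 0.28 * min(a, b)
        if cls == 2:
            hx, hy = cx, cy - 0.85 * b
        elif cls == 3:
            hx = cx - 0.85 * a if cx < spec.width / 2 else cx + 0.85 * a
            hy = cy
        else:
            ang = rng.uniform(0, 2 * np.pi)
            hx, hy = cx + 0.7 * a * np.cos(ang), cy + 0.7 * b * np.sin(ang)
        _ellipse(img, hx, hy, hr, hr, (max(0.0, fleece - 60),) * 3)
        annotations.append(DetectionRecord(image_id=f"scene_{spec.seed}", class_id=int(cls), box=box))

    if spec.illumination == "night":
        img = img * 0.32 + 18.0  # gain reduction + pedestal (contrast compression)
        img += rng.normal(0, 5.0, size=img.shape)  # sensor noise

    img = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticScene(img, annotations, spec)


def _spec_for_index(i: int, rng, width, height, class_probs, day_fraction,
                    occlusion_level, n_range, summer_fraction):
    night = rng.uniform() >= day_fraction
    season = "summer" if rng.uniform() < summer_fraction else "winter"
    probs = np.asarray(class_probs, dtype=np.float64)
    if night and probs[3] > 0:
        probs = probs.copy()
        probs[3] = 0.0  # no nocturnal drinking by default
        probs /= probs.sum()
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    return SceneSpec(
        width=width, height=height, n_instances=n, class_probs=tuple(probs),
        illumination="night" if night else "day", season=season,
        occlusion_level=occlusion_level, seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_scenes(
    n_images: int,
    seed: int,
    width: int = 640,
    height: int = 640,
    class_probs=None,
    day_fraction: float = 0.7,
    summer_fraction: float = 0.5,
    occlusion_level: float = 0.3,
    n_range=(5, MAX_DENSITY),
) -> list:
    """Generate scenes in memory with per-image randomized specs.

    Instance counts are uniform on ``n_range`` (truncated at the density
    ceiling of 36); illumination day/night by ``day_fraction``; season by
    ``summer_fraction``.  Returns a list of (image_id, SyntheticScene).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if class_probs is None:
        class_probs = default_class_probs()
    if n_range[1] > MAX_DENSITY:
        raise ValueError(f"instance counts may not exceed the density ceiling {MAX_DENSITY}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_images):
        spec = _spec_for_index(i, rng, width, height, class_probs, day_fraction,
                               occlusion_level, n_range, summer_fraction)
        scene = generate_scene(spec)
        image_id = f"img{i:04d}_{spec.illumination}_{spec.season}"
        anns = [replace(r, image_id=image_id) for r in scene.annotations]
        out.append((image_id, SyntheticScene(scene.image, anns, spec)))
    return out


def scenes_to_annotated(scenes) -> list:
    """(image_id, SyntheticScene) pairs -> AnnotatedImages (ground truth)."""
    images = []
    for image_id, scene in scenes:
        images.append(
            AnnotatedImage(
                image_id=image_id,
                width=scene.spec.width,
                height=scene.spec.height,
                records=list(scene.annotations),
                capture_tag=scene.spec.illumination,
                season_tag=scene.spec.season,
            )
        )
    return images


def generate_dataset(
    n_images: int,
    out_dir,
    seed: int,
    split_ratio: float = 0.75,
    **scene_kwargs,
) -> SplitManifest:
    """Write a dataset to disk: PNG images, YOLO-txt labels, split manifest."""
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    scenes = generate_scenes(n_images, seed, **scene_kwargs)
    images = scenes_to_annotated(scenes)
    for (image_id, scene), _ in zip(scenes, images):
        Image.fromarray(scene.image).save(out_dir / "images" / f"{image_id}.png")
    write_yolo_txt(images, out_dir / "labels")
    manifest = (
        split_dataset_ids(images, split_ratio, seed)
        if n_images >= 2
        else SplitManifest([images[0].image_id], [], split_ratio, seed)
    )
    manifest.to_json(out_dir / "split.json")
    sizes = {im.image_id: [im.width, im.height] for im in images}
    (out_dir / "sizes.json").write_text(json.dumps(sizes, indent=0))
    return manifest


def split_dataset_ids(images, ratio, seed):
    from .datasets_io import split_dataset

    return split_dataset(images, ratio, seed, stratify_by="capture_tag")
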