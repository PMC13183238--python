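"""Scene generator: determinism, class mixture, occlusion control, outputs."""

import numpy as np
import pytest
from scipy import stats

from ktyolo.evalmetrics import iou_matrix
from ktyolo.synthetic_scenes import (
    MAX_DENSITY,
    REFERENCE_TRAIN_COUNTS,
    PlacementError,
    SceneSpec,
    SyntheticScene,
    default_class_probs,
    generate_dataset,
    generate_scene,
    generate_scenes,
)


class TestSceneSpec:
    def test_rejects_invalid_mixture_and_density(self):
        with pytest.raises(ValueError):
            SceneSpec(class_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SceneSpec(n_instances=MAX_DENSITY + 1)
        with pytest.raises(ValueError):
            SceneSpec(illumination="dusk")

    def test_default_mixture_matches_training_imbalance(self):
        p = default_class_probs()
        c = np.array(REFERENCE_TRAIN_COUNTS, float)
        assert p == pytest.approx(c / c.sum())
        assert p[3] < 0.03  # drinking is the rare class


class TestGenerateScene:
    def test_same_spec_and_seed_is_bit_identical(self):
        spec = SceneSpec(width=160, height=160, n_instances=8, seed=42)
        a, b = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(a.image, b.image)
        assert [r.box for r in a.annotations] == [r.box for r in b.annotations]
        c = generate_scene(SceneSpec(width=160, height=160, n_instances=8, seed=43))
        assert not np.array_equal(a.image, c.image)

    def test_degenerate_mixture_yields_single_class(self):
        spec = SceneSpec(width=160, height=160, n_instances=6,
                         class_probs=(1.0, 0.0, 0.0, 0.0), seed=1)
        scene = generate_scene(spec)
        assert all(r.class_id == 0 for r in scene.annotations)

    def test_annotation_count_and_bounds(self):
        spec = SceneSpec(width=200, height=150, n_instances=10, seed=7)
        scene = generate_scene(spec)
        assert len(scene.annotations) == 10
        for r in scene.annotations:
            x1, y1, x2, y2 = r.box
            assert 0 <= x1 < x2 <= 200 and 0 <= y1 < y2 <= 150

    def test_occlusion_cap_is_respected(self):
        for seed in range(5):
            spec = SceneSpec(width=256, height=256, n_instances=14,
                             occlusion_level=0.25, seed=seed)
            boxes = np.array([r.box for r in generate_scene(spec).annotations])
            m = iou_matrix(boxes, boxes)
            np.fill_diagonal(m, 0.0)
            assert m.max() <= 0.25 + 1e-9

    def test_impossible_density_reports_achieved_count(self):
        spec = SceneSpec(width=64, height=64, n_instances=36,
                         occlusion_level=0.0, seed=0)
        with pytest.raises(PlacementError) as e:
            generate_scene(spec)
        assert 0 <= e.value.achieved < 36

    def test_night_mode_darkens_the_scene(self):
        day = generate_scene(SceneSpec(width=128, height=128, n_instances=5, seed=3))
        night = generate_scene(SceneSpec(width=128, height=128, n_instances=5,
                                         illumination="night", seed=3))
        assert night.image.mean() < 0.6 * day.image.mean()

    def test_class_mixture_converges_to_reference_proportions(self):
        # 10,000 class draws against the training-set multinomial
        probs = default_class_probs()
        rng = np.random.default_rng(12345)
        draws = rng.choice(4, size=10_000, p=probs)
        counts = np.bincount(draws, minlength=4)
        # within 3 standard errors per class
        n = counts.sum()
        for k in range(4):
            se = np.sqrt(probs[k] * (1 - probs[k]) / n)
            assert abs(counts[k] / n - probs[k]) <= 3 * se
        chi2 = stats.chisquare(counts, probs * n)
        assert chi2.pvalue > 0.01

    def test_scene_level_class_sampling_uses_the_mixture(self):
        # aggregate over many small scenes; day-only so drinking is kept
        scenes = generate_scenes(120, seed=77, width=128, height=128,
                                 n_range=(4, 8), day_fraction=1.0)
        classes = [r.class_id for _, s in scenes for r in s.annotations]
        counts = np.bincount(classes, minlength=4)
        n = counts.sum()
        probs = default_class_probs()
        chi2 = stats.chisquare(counts, probs * n)
        assert chi2.pvalue > 0.01


class TestGenerateDataset:
    def test_directory_tree_is_deterministic(self, tmp_path):
        m1 = generate_dataset(6, tmp_path / "a", seed=5, width=96, height=96, n_range=(2, 5))
        m2 = generate_dataset(6, tmp_path / "b", seed=5, width=96, height=96, n_range=(2, 5))
        assert m1.train_ids == m2.train_ids
        for rel in ["labels/img0000_day_winter.txt", "split.json", "sizes.json"]:
            fa, fb = tmp_path / "a" / rel, tmp_path / "b" / rel
            if fa.exists():
                assert fa.read_bytes() == fb.read_bytes()
        imgs_a = sorted((tmp_path / "a" / "images").iterdir())
        imgs_b = sorted((tmp_path / "b" / "images").iterdir())
        assert [p.name for p in imgs_a] == [p.name for p in imgs_b]
        assert all(pa.read_bytes() == pb.read_bytes() for pa, pb in zip(imgs_a, imgs_b))

    def test_day_fraction_one_has_no_night_images(self, tmp_path):
        scenes = generate_scenes(20, seed=9, width=96, height=96,
                                 n_range=(2, 4), day_fraction=1.0)
        assert all(s.spec.illumination == "day" for _, s in scenes)

    def test_no_nocturnal_drinking_by_default(self):
        scenes = generate_scenes(40, seed=13, width=96, height=96,
                                 n_range=(2, 6), day_fraction=0.0)
        for _, s in scenes:
            assert all(r.class_id != 3 for r in s.annotations)

    def test_instance_counts_never_exceed_density_ceiling(self):
        with pytest.raises(ValueError):
            generate_scenes(2, seed=0, n_range=(5, 40))
        scenes = generate_scenes(30, seed=21, width=640, height=640, n_range=(5, 36))
        assert all(1 <= len(s.annotations) <= 36 for _, s in scenes)
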