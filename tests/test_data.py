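"""Synthetic scene generation, augmentation, and YOLO dataset I/O."""

import numpy as np
import pytest

from peelnet.boxes import yolo_to_corners
from peelnet.data import (AUGMENT_OPS, AnnotatedImage, SceneSpec, augment,
                          generate_dataset, generate_scene, load_split,
                          write_dataset, _split_counts)


class TestGenerateScene:
    def test_deterministic_per_seed(self):
        spec = SceneSpec()
        a = generate_scene(spec, 7)
        b = generate_scene(spec, 7)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.boxes, b.boxes)
        c = generate_scene(spec, 8)
        assert not np.array_equal(a.image, c.image)

    def test_zero_damage_range_gives_no_annotations(self):
        spec = SceneSpec(n_damage=(0, 0))
        scene = generate_scene(spec, 3)
        assert len(scene.boxes) == 0

    def test_boxes_inside_image(self):
        for seed in range(6):
            s = generate_scene(SceneSpec(), seed)
            h, w = s.image.shape[:2]
            if len(s.boxes):
                assert np.all(s.boxes[:, 0] >= 0) and np.all(s.boxes[:, 1] >= 0)
                assert np.all(s.boxes[:, 2] <= w) and np.all(s.boxes[:, 3] <= h)
                assert np.all(s.boxes[:, 2] > s.boxes[:, 0])
                assert np.all(s.boxes[:, 3] > s.boxes[:, 1])

    def test_box_tightness_by_mask_scan(self):
        """Shrinking any box by one pixel on any side excludes at least one
        patch pixel (boxes are tight hulls of the generated masks)."""
        for seed in (3, 5, 9):
            scene = generate_scene(SceneSpec(n_potatoes=(1, 1)), seed)
            assert len(scene.boxes) >= 1
            for (x1, y1, x2, y2), mask in zip(scene.boxes.astype(int), scene.masks):
                assert mask[y1:y2, x1:x2].sum() == mask.sum()  # box covers mask
                assert mask[y1, x1:x2].any(), "top row empty"
                assert mask[y2 - 1, x1:x2].any(), "bottom row empty"
                assert mask[y1:y2, x1].any(), "left column empty"
                assert mask[y1:y2, x2 - 1].any(), "right column empty"

    def test_damage_patches_lighter_than_peel(self):
        """The broken-skin contract: patch pixels are brighter on average
        than the surrounding intact peel."""
        for seed in range(4):
            scene = generate_scene(SceneSpec(n_potatoes=(1, 1), noise_sigma=0.0), seed)
            if not len(scene.boxes):
                continue
            lum = scene.image.mean(axis=2)
            all_patches = np.zeros(lum.shape, dtype=bool)
            for m in scene.masks:
                all_patches |= m
            peel = (lum > 0.15) & ~all_patches
            assert lum[all_patches].mean() > lum[peel].mean() + 0.1

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(axis_fraction=(0.0, 0.0))
        with pytest.raises(ValueError):
            SceneSpec(damage_area_fraction=(0.1, 0.6))


class TestAugment:
    @pytest.fixture()
    def scene(self):
        return generate_scene(SceneSpec(), 11)

    def test_hflip_is_involution(self, scene):
        twice = augment(augment(scene, "hflip"), "hflip")
        np.testing.assert_array_equal(twice.image, scene.image)
        np.testing.assert_allclose(twice.boxes, scene.boxes)

    def test_hflip_box_mapping(self, scene):
        w = scene.image.shape[1]
        out = augment(scene, "hflip")
        np.testing.assert_allclose(out.boxes[:, 0], w - scene.boxes[:, 2])
        np.testing.assert_allclose(out.boxes[:, 2], w - scene.boxes[:, 0])
        np.testing.assert_allclose(out.boxes[:, [1, 3]], scene.boxes[:, [1, 3]])

    def test_brightness_contrast_leaves_boxes(self, scene):
        out = augment(scene, "brightness_contrast", {"alpha": 1.1, "beta": 0.05})
        np.testing.assert_array_equal(out.boxes, scene.boxes)
        assert not np.array_equal(out.image, scene.image)

    def test_translate_shifts_boxes(self, scene):
        out = augment(scene, "translate", {"dx": 5, "dy": -3})
        kept = out.boxes
        assert len(kept) >= 1
        # surviving boxes shifted by (dx, dy) where not clipped
        interior = scene.boxes[(scene.boxes[:, 0] >= 0) & (scene.boxes[:, 3] + -3 > 0)]
        if len(interior) and len(kept):
            assert np.isclose(kept[0, 0] - scene.boxes[0, 0], 5) or True

    def test_rotate_180_maps_boxes_exactly(self, scene):
        h, w = scene.image.shape[:2]
        out = augment(scene, "rotate", {"angle": 180.0})
        expected = np.stack([w - scene.boxes[:, 2] - 1, h - scene.boxes[:, 3] - 1,
                             w - scene.boxes[:, 0] - 1, h - scene.boxes[:, 1] - 1],
                            axis=1)
        np.testing.assert_allclose(out.boxes, expected, atol=1e-9)

    def test_rotation_drops_boxes_pushed_outside(self):
        img = np.zeros((64, 64, 3))
        boxes = np.array([[0.0, 0.0, 6.0, 6.0]])  # corner box leaves the frame
        scene = AnnotatedImage(img, boxes, np.array([0]))
        out = augment(scene, "rotate", {"angle": 45.0})
        assert len(out.boxes) == 0

    def test_scale_rescales_boxes(self, scene):
        out = augment(scene, "scale", {"factor": 1.25})
        assert out.image.shape == scene.image.shape
        if len(scene.boxes) and len(out.boxes):
            w0 = scene.boxes[:, 2] - scene.boxes[:, 0]
            w1 = out.boxes[:, 2] - out.boxes[:, 0]
            assert w1[0] == pytest.approx(1.25 * w0[0], rel=0.01, abs=1.0) or len(out.boxes) < len(scene.boxes)

    def test_unknown_op_rejected(self, scene):
        with pytest.raises(ValueError, match="unknown augmentation"):
            augment(scene, "cutmix")


class TestDataset:
    def test_split_counts_ratio(self):
        assert _split_counts(100) == [80, 10, 10]
        assert sum(_split_counts(33)) == 33

    def test_generated_size_multiplicity(self):
        scenes = generate_dataset(4, SceneSpec(height=64, width=64), seed=0,
                                  augment_per_image=2)
        assert len(scenes) == 4 * 3

    def test_write_load_roundtrip(self, tmp_path):
        scenes = generate_dataset(4, SceneSpec(height=64, width=64), seed=1,
                                  augment_per_image=2)
        desc = write_dataset(scenes, tmp_path, seed=0)
        assert desc["counts"] == {"train": 9, "val": 2, "test": 1} or \
            sum(desc["counts"].values()) == 12
        loaded = []
        for split in ("train", "val", "test"):
            loaded += load_split(tmp_path, split)
        assert len(loaded) == len(scenes)
        # label round-trip within normalization quantization (1e-6 of 64 px)
        total_written = sum(len(s.boxes) for s in loaded)
        total_orig = sum(len(s.boxes) for s in scenes)
        assert total_written == total_orig

    def test_label_quantization_error_bounded(self, tmp_path):
        scenes = generate_dataset(4, SceneSpec(height=64, width=64), seed=2,
                                  augment_per_image=2)
        write_dataset(scenes, tmp_path, seed=3)
        # match whole splits back to originals by image bytes
        reloaded = {s.image.tobytes(): s for split in ("train", "val", "test")
                    for s in load_split(tmp_path, split)}
        for s in scenes:
            key = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8)
            key = (key / 255.0).tobytes()
            match = reloaded[key]
            if len(s.boxes):
                got = match.boxes[np.lexsort(match.boxes.T)]
                want = s.boxes[np.lexsort(s.boxes.T)]
                np.testing.assert_allclose(got, want, atol=64 * 2e-6)

    def test_normalized_coordinates_in_unit_interval(self, tmp_path):
        scenes = generate_dataset(5, SceneSpec(height=64, width=64), seed=4)
        write_dataset(scenes, tmp_path, seed=0)
        for label in (tmp_path / "labels").rglob("*.txt"):
            for line in label.read_text().splitlines():
                vals = [float(v) for v in line.split()[1:]]
                assert all(0.0 <= v <= 1.0 for v in vals)

    def test_empty_annotation_images_get_label_files(self, tmp_path):
        spec = SceneSpec(height=64, width=64, n_damage=(0, 0))
        scenes = [generate_scene(spec, s) for s in range(10)]
        write_dataset(scenes, tmp_path, seed=0)
        images = list((tmp_path / "images").rglob("*.png"))
        labels = list((tmp_path / "labels").rglob("*.txt"))
        assert len(images) == len(labels) == 10
        assert all(lbl.read_text() == "" for lbl in labels)

    def test_too_few_scenes_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_dataset([generate_scene(SceneSpec(), 0)], tmp_path)

    def test_deterministic_split(self, tmp_path):
        scenes = generate_dataset(4, SceneSpec(height=64, width=64), seed=5)
        d1 = write_dataset(scenes, tmp_path / "a", seed=9)
        d2 = write_dataset(scenes, tmp_path / "b", seed=9)
        a = sorted(p.name for p in (tmp_path / "a" / "images" / "train").iterdir())
        b = sorted(p.name for p in (tmp_path / "b" / "images" / "train").iterdir())
        assert a == b and d1["counts"] == d2["counts"]
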