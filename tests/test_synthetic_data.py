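"""Synthetic scenes: determinism, label fidelity, splits, augmentation, rebalance."""

import json

import numpy as np
import pytest
from PIL import Image

from rdwkit.boxes import BoxXYWH, read_yolo_labels, write_yolo_labels
from rdwkit.synthetic_data import (
    AUG_OPS,
    AugSpec,
    DatasetLayout,
    SceneConfig,
    augment_image,
    generate_dataset,
    generate_scene,
    longtail_counts,
    rebalance_dataset,
    split_counts,
)


class TestSceneGeneration:
    def test_deterministic_given_seed(self):
        cfg = SceneConfig(seed=42)
        img1, lbl1 = generate_scene(cfg, 7)
        img2, lbl2 = generate_scene(cfg, 7)
        assert np.array_equal(img1, img2)
        assert lbl1 == lbl2
        img3, _ = generate_scene(cfg, 8)
        assert not np.array_equal(img1, img3)

    def test_labels_are_tight_mask_bboxes(self):
        cfg = SceneConfig(seed=3, objects_per_image=(2, 3))
        h, w = cfg.image_size
        for scene_seed in range(5):
            _, labels, masks = generate_scene(cfg, scene_seed, return_masks=True)
            assert labels
            for (cls, box), mask in zip(labels, masks):
                ys, xs = np.nonzero(mask)
                expect = BoxXYWH(
                    cx=(xs.min() + xs.max() + 1) / 2 / w,
                    cy=(ys.min() + ys.max() + 1) / 2 / h,
                    w=(xs.max() + 1 - xs.min()) / w,
                    h=(ys.max() + 1 - ys.min()) / h,
                )
                assert box.as_tuple() == pytest.approx(expect.as_tuple(), abs=1e-12)

    def test_zero_counts_give_empty_scene(self):
        cfg = SceneConfig(seed=1, objects_per_image=(0, 0))
        img, labels = generate_scene(cfg, 0)
        assert labels == []
        assert img.shape == (*cfg.image_size, 3)

    def test_boxes_inside_unit_square(self):
        cfg = SceneConfig(seed=5, objects_per_image=(3, 3), overlap_allowed=True)
        for s in range(10):
            _, labels = generate_scene(cfg, s)
            for _, b in labels:
                x1, y1, x2, y2 = b.to_corners()
                assert -1e-9 <= x1 and x2 <= 1 + 1e-9
                assert -1e-9 <= y1 and y2 <= 1 + 1e-9


class TestLongTail:
    def test_counts_are_monotone_decreasing(self):
        counts = longtail_counts(6, exponent=1.5)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] > counts[-1]

    def test_empirical_histogram_tracks_target_proportions(self):
        probs = SceneConfig(num_classes=4, per_class_counts=(60, 25, 10, 5), seed=9).class_probs()
        cfg = SceneConfig(
            num_classes=4, per_class_counts=(60, 25, 10, 5), seed=9,
            objects_per_image=(2, 3), image_size=(32, 32),
        )
        hist = np.zeros(4)
        for s in range(300):
            _, labels = generate_scene(cfg, s)
            for cls, _ in labels:
                hist[cls] += 1
        n = hist.sum()
        emp = hist / n
        # 4-sigma multinomial band per class
        for k in range(4):
            sigma = np.sqrt(probs[k] * (1 - probs[k]) / n)
            assert abs(emp[k] - probs[k]) < 4 * sigma + 1e-9


class TestSplit:
    @pytest.mark.parametrize(
        "n, expected",
        [
            (100, (70, 20, 10)),
            (10, (7, 2, 1)),
            # largest-remainder: quotas 17610.6 / 5031.6 / 2515.8 — the 0.8
            # remainder seats first, the 0.6 tie goes to the earlier split
            (25158, (17611, 5031, 2516)),
        ],
    )
    def test_largest_remainder_examples(self, n, expected):
        assert split_counts(n) == expected

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 10_000))
            parts = split_counts(n)
            assert sum(parts) == n
            for p, r in zip(parts, (0.7, 0.2, 0.1)):
                assert abs(p - n * r) < 1.0

    def test_dataset_layout_on_disk(self, small_dataset):
        man = small_dataset.manifest
        assert man["split_counts"] == {"train": 21, "val": 6, "test": 3}
        ids = [i for s in ("train", "val", "test") for i in man["splits"][s]]
        assert len(ids) == len(set(ids)) == 30  # disjoint and exhaustive
        for split in ("train", "val", "test"):
            for image_id in small_dataset.image_ids(split):
                assert (small_dataset.images_dir(split) / f"{image_id}.png").exists()
                labels = read_yolo_labels(small_dataset.labels_dir(split) / f"{image_id}.txt")
                for cls, box in labels:
                    assert 0 <= cls < man["config"]["num_classes"]

    def test_refuses_nonempty_dir(self, tmp_path):
        (tmp_path / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_dataset(SceneConfig(), 10, tmp_path)

    def test_label_round_trip(self, tmp_path):
        labels = [(0, BoxXYWH(0.5, 0.5, 0.25, 0.125)), (3, BoxXYWH(0.1, 0.9, 0.05, 0.05))]
        path = tmp_path / "x.txt"
        write_yolo_labels(path, labels)
        back = read_yolo_labels(path)
        assert [c for c, _ in back] == [c for c, _ in labels]
        for (_, a), (_, b) in zip(back, labels):
            assert a.as_tuple() == pytest.approx(b.as_tuple(), abs=1e-6)


class TestAugmentation:
    @pytest.mark.parametrize("op", ["brightness", "contrast", "saturation", "gaussian_blur", "detail_enhance"])
    def test_photometric_ops_leave_labels_untouched(self, op):
        img, labels = generate_scene(SceneConfig(seed=2), 0)
        out, out_labels = augment_image(img, labels, AugSpec(op))
        assert out_labels == labels
        assert out.shape == img.shape

    def test_rotate_90_box_map(self):
        img, _ = generate_scene(SceneConfig(seed=2), 0)
        box = BoxXYWH(0.25, 0.125, 0.1, 0.2)
        _, out = augment_image(img, [(0, box)], AugSpec("rotate", 90))
        assert out[0][1].as_tuple() == pytest.approx((1 - 0.125, 0.25, 0.2, 0.1), abs=1e-12)

    def test_rotate_round_trip(self):
        img, labels = generate_scene(SceneConfig(seed=2, objects_per_image=(2, 2)), 1)
        r1, l1 = augment_image(img, labels, AugSpec("rotate", 90))
        r2, l2 = augment_image(r1, l1, AugSpec("rotate", -90))
        assert np.array_equal(r2, img)
        for (c1, b1), (c2, b2) in zip(labels, l2):
            assert c1 == c2
            assert max(abs(a - b) for a, b in zip(b1.as_tuple(), b2.as_tuple())) < 1e-9

    def test_rotated_labels_match_rotated_masks(self):
        """Geometric augmentation keeps labels glued to the rendered objects."""
        cfg = SceneConfig(seed=4, objects_per_image=(2, 2))
        h, w = cfg.image_size
        img, labels, masks = generate_scene(cfg, 0, return_masks=True)
        _, rot_labels = augment_image(img, labels, AugSpec("rotate", 90))
        for (_, box), mask in zip(rot_labels, masks):
            rmask = np.rot90(mask, k=-1)
            ys, xs = np.nonzero(rmask)
            assert box.cx * w == pytest.approx((xs.min() + xs.max() + 1) / 2, abs=1e-9)
            assert box.cy * h == pytest.approx((ys.min() + ys.max() + 1) / 2, abs=1e-9)

    def test_non_quarter_rotation_rejected(self):
        img, labels = generate_scene(SceneConfig(seed=2), 0)
        with pytest.raises(ValueError):
            augment_image(img, labels, AugSpec("rotate", 45))

    def test_unknown_op_rejected(self):
        with pytest.raises(ValueError):
            AugSpec("mosaic")


class TestRebalance:
    def _make_layout(self, tmp_path, n=30):
        cfg = SceneConfig(
            image_size=(32, 32), num_classes=4,
            per_class_counts=(40, 10, 4, 2), seed=13,
        )
        return generate_dataset(cfg, n, tmp_path / "ds")

    def test_floor_is_reached(self, tmp_path):
        layout = self._make_layout(tmp_path)
        before = layout.class_instance_counts()
        floor = max(before.values())  # forces augmentation of every minority class
        layout, report = rebalance_dataset(layout, min_per_class=floor, max_multiplier=50)
        after = layout.class_instance_counts()
        assert report["added_images"] > 0
        for cls in before:
            if cls not in report["unbalanceable"]:
                assert after[cls] >= floor

    def test_no_change_when_already_balanced(self, tmp_path):
        layout = self._make_layout(tmp_path)
        before = layout.class_instance_counts()
        layout, report = rebalance_dataset(layout, min_per_class=1)
        assert report["added_images"] == 0
        assert layout.class_instance_counts() == before

    def test_absent_class_reported(self, tmp_path):
        cfg = SceneConfig(
            image_size=(32, 32), num_classes=5,
            per_class_counts=(50, 30, 20, 1, 1), seed=2, objects_per_image=(1, 1),
        )
        layout = generate_dataset(cfg, 12, tmp_path / "ds")
        missing = [c for c in range(5) if c not in layout.class_instance_counts()]
        if not missing:
            pytest.skip("all classes present for this seed")
        _, report = rebalance_dataset(layout, min_per_class=5)
        assert set(missing) <= set(report["unbalanceable"])

    def test_provenance_recorded(self, tmp_path):
        layout = self._make_layout(tmp_path)
        layout, report = rebalance_dataset(layout, min_per_class=8, max_multiplier=50)
        if report["added_images"] == 0:
            pytest.skip("no augmentation needed for this seed")
        prov = layout.manifest["provenance"]
        assert len(prov) == report["added_images"]
        for new_id, entry in prov.items():
            assert entry["op"] in AUG_OPS
            assert (layout.images_dir("train") / f"{new_id}.png").exists()
            assert (layout.labels_dir("train") / f"{new_id}.txt").exists()


def test_manifest_round_trip(small_dataset):
    loaded = DatasetLayout.load(small_dataset.root)
    assert loaded.manifest == small_dataset.manifest
    cfg = SceneConfig.from_dict(loaded.manifest["config"])
    assert cfg.num_classes == 4
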