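"""Synthetic scene generator, mosaic augmentation, splitting, label I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmtb import metrics as M
from lmtb import scenes as S


class TestGenerateScene:
    def test_same_seed_bit_identical(self):
        spec = S.SceneSpec(image_size=160, n_targets=10, seed=7)
        img1, ann1 = S.generate_scene(spec)
        img2, ann2 = S.generate_scene(spec)
        np.testing.assert_array_equal(img1, img2)
        np.testing.assert_array_equal(ann1, ann2)

    def test_different_seed_differs(self):
        a = S.generate_scene(S.SceneSpec(image_size=160, n_targets=10, seed=1))[0]
        b = S.generate_scene(S.SceneSpec(image_size=160, n_targets=10, seed=2))[0]
        assert not np.array_equal(a, b)

    def test_boxes_inside_unit_square_with_positive_area(self):
        _, anns = S.generate_scene(S.SceneSpec(n_targets=30, seed=3))
        assert len(anns) == 30
        x1 = anns[:, 1] - anns[:, 3] / 2
        y1 = anns[:, 2] - anns[:, 4] / 2
        x2 = anns[:, 1] + anns[:, 3] / 2
        y2 = anns[:, 2] + anns[:, 4] / 2
        assert np.all(x1 >= -1e-9) and np.all(y1 >= -1e-9)
        assert np.all(x2 <= 1 + 1e-9) and np.all(y2 <= 1 + 1e-9)
        assert np.all(anns[:, 3] > 0) and np.all(anns[:, 4] > 0)

    def test_scale_spread_realised_in_emitted_boxes(self):
        _, anns = S.generate_scene(S.SceneSpec(n_targets=30, scale_spread=5.0, seed=11))
        sides = np.maximum(anns[:, 3], anns[:, 4])
        assert sides.max() / sides.min() >= 4.0

    def test_low_contrast_foreground(self):
        """Bud pixels sit close to the background lightness (camouflage)."""
        spec = S.SceneSpec(n_targets=20, seed=5)
        img, _ = S.generate_scene(spec)
        bg = S.generate_scene(
            S.SceneSpec(n_targets=0, seed=5, illumination=spec.illumination)
        )[0]
        diff = abs(float(img.mean()) - float(bg.mean()))
        assert diff < 25.0

    def test_impossible_packing_raises_diagnostic(self):
        spec = S.SceneSpec(image_size=64, n_targets=3, min_size=200, seed=0)
        with pytest.raises(RuntimeError, match="could not place"):
            S.generate_scene(spec)


class TestMosaic:
    def _sample(self, size=64):
        img = np.full((size, size, 3), 50, dtype=np.uint8)
        ann = np.array([[0, 0.5, 0.5, 0.25, 0.25]])
        return img, ann

    def test_four_identical_centred_boxes_give_one_per_quadrant(self):
        size, seed = 64, 0
        canvas, anns = S.mosaic_augment([self._sample(size)] * 4, seed=seed)
        assert len(anns) == 4
        rng = np.random.default_rng(seed)
        xc = int(rng.uniform(0.3 * size, 0.7 * size)) / size
        yc = int(rng.uniform(0.3 * size, 0.7 * size)) / size
        quads = [(0, 0, xc, yc), (xc, 0, 1, yc), (0, yc, xc, 1), (xc, yc, 1, 1)]
        for (qx1, qy1, qx2, qy2), (c, cx, cy, w, h) in zip(quads, anns):
            assert qx1 - 1e-9 <= cx - w / 2 and cx + w / 2 <= qx2 + 1e-9
            assert qy1 - 1e-9 <= cy - h / 2 and cy + h / 2 <= qy2 + 1e-9

    def test_label_count_never_exceeds_input_total(self, rng):
        for seed in range(10):
            samples = [
                S.generate_scene(S.SceneSpec(image_size=96, min_size=6, n_targets=6, seed=seed * 4 + k))
                for k in range(4)
            ]
            _, anns = S.mosaic_augment(samples, seed=seed)
            assert len(anns) <= sum(len(a) for _, a in samples)
            if len(anns):
                assert anns[:, 1:].min() >= -1e-9 and anns[:, 1:].max() <= 1 + 1e-9

    def test_labels_match_corner_transform_oracle(self):
        """Surviving boxes agree (IoU >= 0.99) with direct corner transforms."""
        samples = [
            S.generate_scene(S.SceneSpec(image_size=96, min_size=6, n_targets=5, seed=40 + k))
            for k in range(4)
        ]
        seed = 3
        canvas, anns = S.mosaic_augment(samples, seed=seed)
        s = 96
        rng = np.random.default_rng(seed)
        xc = int(rng.uniform(0.3 * s, 0.7 * s))
        yc = int(rng.uniform(0.3 * s, 0.7 * s))
        offs = [(xc - s, yc - s), (xc, yc - s), (xc - s, yc), (xc, yc)]
        quads = [(0, 0, xc, yc), (xc, 0, s, yc), (0, yc, xc, s), (xc, yc, s, s)]
        oracle = []
        for (img, ann), (dx, dy), (qx1, qy1, qx2, qy2) in zip(samples, offs, quads):
            for c, cx, cy, w, h in ann:
                corners = np.array([
                    [cx * s - w * s / 2 + dx, cy * s - h * s / 2 + dy],
                    [cx * s + w * s / 2 + dx, cy * s + h * s / 2 + dy],
                ])
                x1 = max(corners[0, 0], qx1); y1 = max(corners[0, 1], qy1)
                x2 = min(corners[1, 0], qx2); y2 = min(corners[1, 1], qy2)
                if x2 - x1 >= 2 and y2 - y1 >= 2:
                    oracle.append([(x1 + x2) / 2 / s, (y1 + y2) / 2 / s,
                                   (x2 - x1) / s, (y2 - y1) / s])
        oracle = np.asarray(oracle)
        assert len(oracle) == len(anns)
        iou = M.box_iou_xywh(anns[:, 1:5], oracle)
        assert np.all(iou.max(axis=1) >= 0.99)

    def test_fewer_than_four_samples_rejected(self):
        with pytest.raises(ValueError):
            S.mosaic_augment([self._sample()] * 3, seed=0)


class TestSplit:
    def test_paper_scale_split_counts(self):
        train, test, val = S.split_dataset(range(3062), (0.7, 0.2, 0.1), seed=0)
        assert (len(train), len(test), len(val)) == (2143, 613, 306)

    def test_ten_items(self):
        train, test, val = S.split_dataset(range(10), seed=0)
        assert (len(train), len(test), len(val)) == (7, 2, 1)

    @given(st.integers(1, 2000), st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_splits_partition_the_input(self, n, seed):
        items = list(range(n))
        train, test, val = S.split_dataset(items, seed=seed)
        merged = train + test + val
        assert len(merged) == n
        assert set(merged) == set(items)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            S.split_dataset(range(10), (0.5, 0.2, 0.1), seed=0)

    def test_seed_determinism(self):
        a = S.split_dataset(range(100), seed=5)
        b = S.split_dataset(range(100), seed=5)
        assert a == b


class TestLabelIO:
    def test_round_trip_to_1e9(self, tmp_path, rng):
        anns = np.column_stack([
            np.zeros(7), rng.uniform(0.2, 0.8, (7, 2)), rng.uniform(0.01, 0.2, (7, 2))
        ])
        p = tmp_path / "x.txt"
        S.write_yolo_labels(p, anns)
        back = S.read_yolo_labels(p)
        np.testing.assert_allclose(back, anns, atol=1e-9)

    def test_empty_file_round_trip(self, tmp_path):
        p = tmp_path / "e.txt"
        S.write_yolo_labels(p, np.zeros((0, 5)))
        assert S.read_yolo_labels(p).shape == (0, 5)

    def test_generate_dataset_writes_manifest(self, tmp_path):
        man = S.generate_dataset(
            tmp_path, 10, seed=1, spec=S.SceneSpec(image_size=96, min_size=6, n_targets=4)
        )
        counts = {k: len(v) for k, v in man["splits"].items()}
        assert counts == {"train": 7, "test": 2, "val": 1}
        assert len(list((tmp_path / "images").glob("*.png"))) == 10
        back = S.read_yolo_labels(next(iter((tmp_path / "labels").glob("*.txt"))))
        assert back.shape[1] == 5
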