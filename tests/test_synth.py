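"""Synthetic scene generation, label IO, splitting and offline expansion."""

import numpy as np
import pytest

from leafdet.assign import GroundTruthBox
from leafdet.synth import (
    SynthConfig,
    expand_dataset,
    generate_scene,
    read_labels,
    split_dataset,
    write_labels,
)


class TestGenerateScene:
    def test_zero_lesions_gives_empty_labels(self):
        cfg = SynthConfig(image_size=64, lesions_per_image=(0, 0), seed=0)
        scene = generate_scene(cfg, np.random.default_rng(0))
        assert scene.boxes == [] and scene.image.shape == (64, 64, 3)

    def test_boxes_tight_around_rendered_masks(self):
        cfg = SynthConfig(
            image_size=128, lesions_per_image=(3, 6), lesion_size_range=(30, 120),
        )
        scene = generate_scene(cfg, np.random.default_rng(2))
        assert scene.boxes and scene.masks is not None
        for b, m in zip(scene.boxes, scene.masks):
            ys, xs = np.nonzero(m)
            x1, x2 = xs.min(), xs.max() + 1
            y1, y2 = ys.min(), ys.max() + 1
            assert abs((b.cx - b.w / 2) * 128 - x1) <= 1
            assert abs((b.cx + b.w / 2) * 128 - x2) <= 1
            assert abs((b.cy - b.h / 2) * 128 - y1) <= 1
            assert abs((b.cy + b.h / 2) * 128 - y2) <= 1

    def test_fixed_seed_reproducible(self):
        cfg = SynthConfig(image_size=64, seed=0)
        a = generate_scene(cfg, np.random.default_rng(3))
        b = generate_scene(cfg, np.random.default_rng(3))
        assert np.array_equal(a.image, b.image) and a.boxes == b.boxes

    def test_class_frequencies_roughly_uniform(self):
        cfg = SynthConfig(image_size=64, num_classes=4, lesions_per_image=(4, 8),
                          lesion_size_range=(40, 120))
        rng = np.random.default_rng(5)
        counts = np.zeros(4)
        for _ in range(40):
            for b in generate_scene(cfg, rng).boxes:
                counts[b.class_id] += 1
        total = counts.sum()
        assert total > 100
        # multinomial with p=1/4: allow generous 5-sigma band
        p = counts / total
        sigma = np.sqrt(0.25 * 0.75 / total)
        assert np.all(np.abs(p - 0.25) < 5 * sigma)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(lesion_size_range=(1, 10))
        with pytest.raises(ValueError):
            SynthConfig(num_classes=0)


class TestLabelIO:
    BOXES = [
        GroundTruthBox(3, 0.5, 0.5, 1.0, 1.0),
        GroundTruthBox(0, 0.25, 0.75, 0.1, 0.2),
    ]

    def test_full_image_box_line(self, tmp_path):
        p = tmp_path / "a.txt"
        write_labels([self.BOXES[0]], p)
        assert p.read_text().splitlines()[0] == "3 0.500000 0.500000 1.000000 1.000000"

    def test_yolo_roundtrip_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        for i in range(50):
            boxes = []
            for _ in range(rng.integers(1, 6)):
                w, h = rng.uniform(0.01, 0.5, 2)
                cx = rng.uniform(w / 2, 1 - w / 2)
                cy = rng.uniform(h / 2, 1 - h / 2)
                boxes.append(GroundTruthBox(int(rng.integers(8)), cx, cy, w, h))
            p = tmp_path / f"{i}.txt"
            write_labels(boxes, p)
            back = read_labels(p)
            for a, b in zip(boxes, back):
                assert a.class_id == b.class_id
                assert abs(a.cx - b.cx) < 1e-5 and abs(a.w - b.w) < 1e-5

    def test_voc_roundtrip_within_pixel(self, tmp_path):
        p = tmp_path / "a.xml"
        write_labels(self.BOXES, p, fmt="voc_xml", image_size=(640, 480))
        back = read_labels(p, fmt="voc_xml", image_size=(640, 480))
        for a, b in zip(self.BOXES, back):
            assert a.class_id == b.class_id
            assert abs(a.cx - b.cx) * 640 <= 1.0
            assert abs(a.cy - b.cy) * 480 <= 1.0

    def test_empty_label_file(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert read_labels(p) == []

    def test_malformed_line_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.1 0.1\n1 0.5 0.5\n")
        with pytest.raises(ValueError, match=r"bad\.txt:2"):
            read_labels(p)

    def test_malformed_xml_reported(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation><object>")
        with pytest.raises(ValueError, match="malformed"):
            read_labels(p, fmt="voc_xml", image_size=(10, 10))


class TestSplit:
    def test_expanded_dataset_arithmetic(self):
        split = split_dataset(list(range(4079)), seed=0)
        assert len(split.train) + len(split.val) == 3671
        assert len(split.test) == 408
        assert len(split.val) == 367

    def test_ten_ids_nine_to_one(self):
        split = split_dataset(list(range(10)), seed=1)
        assert len(split.test) == 1
        assert len(split.train) + len(split.val) == 9

    def test_disjoint_and_deterministic(self):
        a = split_dataset(list(range(100)), seed=4)
        b = split_dataset(list(range(100)), seed=4)
        assert a.train == b.train and a.val == b.val and a.test == b.test
        assert not (set(a.train) & set(a.val) | set(a.train) & set(a.test)
                    | set(a.val) & set(a.test))


class TestExpand:
    def _scenes(self, n=5):
        cfg = SynthConfig(image_size=64, num_classes=3, lesions_per_image=(1, 3),
                          lesion_size_range=(60, 160))
        rng = np.random.default_rng(1)
        return [generate_scene(cfg, rng) for _ in range(n)]

    def test_target_equal_to_input_unchanged(self):
        scenes = self._scenes()
        assert expand_dataset(scenes, 5, np.random.default_rng(0)) == scenes

    def test_expansion_reaches_target_count(self):
        scenes = self._scenes()
        out = expand_dataset(scenes, 17, np.random.default_rng(0))
        assert len(out) == 17

    def test_all_expanded_boxes_valid(self):
        out = expand_dataset(self._scenes(), 20, np.random.default_rng(2))
        for s in out:
            for b in s.boxes:
                assert 0 <= b.cx - b.w / 2 and b.cx + b.w / 2 <= 1
                assert 0 <= b.cy - b.h / 2 and b.cy + b.h / 2 <= 1

    def test_flip_preserves_box_areas(self):
        from leafdet.synth import _flip_scene

        scene = self._scenes(1)[0]
        flipped = _flip_scene(scene)
        for a, b in zip(scene.boxes, flipped.boxes):
            assert a.w * a.h == pytest.approx(b.w * b.h, abs=1e-12)

    def test_shrinking_target_rejected(self):
        with pytest.raises(ValueError):
            expand_dataset(self._scenes(), 2, np.random.default_rng(0))
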