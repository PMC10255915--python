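"""Manifests, per-class splitting, frame sampling and optical flow."""

import numpy as np
import pytest

from tsml import (ClipRecord, DatasetManifest, InvalidInputError, IOConfig,
                  compute_flow, sample_indices, split_per_class)
from tsml.data import load_sample, load_split_arrays

# per-class clip counts of a six-behavior video dataset used as the
# bookkeeping reference throughout (fighting, drinking, eating,
# investigating, lying, walking)
SIX_CLASS_COUNTS = {
    "fighting": 605, "drinking": 597, "eating": 607,
    "investigating": 602, "lying": 601, "walking": 594,
}


def manifest_from_counts(counts: dict) -> DatasetManifest:
    records = [
        ClipRecord(path=f"{cls}/{cls}_{i:04d}", label=cls, num_frames=48, fps=25)
        for cls, n in counts.items()
        for i in range(n)
    ]
    return DatasetManifest(records=records, classes=list(counts))


class TestManifest:
    def test_counts_and_total(self):
        m = manifest_from_counts({"a": 5, "b": 3})
        assert m.counts == {"a": 5, "b": 3}
        assert m.total == 8

    def test_six_class_totals(self):
        m = manifest_from_counts(SIX_CLASS_COUNTS)
        assert m.total == 3606

    def test_label_outside_class_list_rejected(self):
        with pytest.raises(InvalidInputError):
            DatasetManifest(
                records=[ClipRecord(path="x", label="zebra")], classes=["a"]
            )

    def test_csv_roundtrip_preserves_class_order(self, tmp_path):
        m = manifest_from_counts({"walking": 3, "drinking": 2})
        m.to_csv(tmp_path / "m.csv")
        loaded = DatasetManifest.from_csv(tmp_path / "m.csv")
        assert loaded.classes == ["walking", "drinking"]
        assert loaded.counts == m.counts

    def test_label_index_follows_class_order(self):
        m = manifest_from_counts({"drinking": 2, "eating": 2})
        assert m.label_index("drinking") == 0
        assert m.label_index("eating") == 1


class TestSplitPerClass:
    def test_eighty_twenty_reproduces_published_totals(self):
        m = split_per_class(manifest_from_counts(SIX_CLASS_COUNTS), 0.8, seed=0)
        train = len(m.subset("train"))
        test = len(m.subset("test"))
        assert train == 2886
        assert test == 720

    def test_round_half_up_on_even_tens(self):
        m = split_per_class(manifest_from_counts({"a": 10, "b": 10}), 0.8, 1)
        assert len(m.subset("train")) == 16
        assert len(m.subset("test")) == 4

    def test_per_class_conservation(self):
        m = split_per_class(manifest_from_counts(SIX_CLASS_COUNTS), 0.8, 3)
        for cls, n in SIX_CLASS_COUNTS.items():
            tr = sum(1 for r in m.subset("train") if r.label == cls)
            te = sum(1 for r in m.subset("test") if r.label == cls)
            assert tr + te == n

    def test_same_seed_identical_split(self):
        base = manifest_from_counts({"a": 9, "b": 7})
        m1 = split_per_class(base, 0.8, 42)
        m2 = split_per_class(base, 0.8, 42)
        assert [r.split for r in m1.records] == [r.split for r in m2.records]

    def test_different_seed_differs(self):
        base = manifest_from_counts({"a": 30})
        m1 = split_per_class(base, 0.5, 1)
        m2 = split_per_class(base, 0.5, 2)
        assert [r.split for r in m1.records] != [r.split for r in m2.records]

    def test_tiny_class_rejected(self):
        with pytest.raises(InvalidInputError):
            split_per_class(manifest_from_counts({"a": 1, "b": 5}), 0.8, 0)


class TestFrameSampling:
    def test_uniform_hundred_to_five(self):
        np.testing.assert_array_equal(
            sample_indices(100, 5, "uniform"), [0, 24, 49, 74, 99]
        )

    def test_all_frames_in_order(self):
        np.testing.assert_array_equal(sample_indices(7, 7, "uniform"), np.arange(7))

    def test_random_mode_deterministic_given_seed(self):
        a = sample_indices(50, 10, "random", seed=3)
        b = sample_indices(50, 10, "random", seed=3)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)  # sorted, no repeats

    def test_too_short_clip_rejected(self):
        with pytest.raises(InvalidInputError):
            sample_indices(4, 5)


class TestComputeFlow:
    @staticmethod
    def textured_square(shift=(0, 0), size=48):
        rng = np.random.default_rng(0)
        frame = np.full((size, size), 0.4, dtype=np.float32)
        patch = rng.random((16, 16)).astype(np.float32)
        r0, c0 = 12 + shift[1], 12 + shift[0]
        frame[r0 : r0 + 16, c0 : c0 + 16] = patch
        return frame

    def test_static_scene_near_zero_flow(self):
        f = self.textured_square()
        flow = compute_flow(np.stack([f, f]))
        assert flow.shape == (1, 48, 48, 2)
        assert np.abs(flow).mean() < 0.1

    @pytest.mark.parametrize("d", [1, 3, 5])
    def test_translation_recovered_within_twenty_percent(self, d):
        a = self.textured_square((0, 0))
        b = self.textured_square((d, 0))
        flow = compute_flow(np.stack([a, b]))
        inside = flow[0, 14:26, 14:26, :]  # interior of the moving square
        assert inside[..., 0].mean() == pytest.approx(d, rel=0.2)
        assert abs(inside[..., 1].mean()) < 0.2 * d + 0.2

    def test_negated_translation_negates_flow(self):
        a = self.textured_square((0, 0))
        fwd = compute_flow(np.stack([a, self.textured_square((3, 0))]))
        bwd = compute_flow(np.stack([a, self.textured_square((-3, 0))]))
        inside_f = fwd[0, 14:26, 14:26, 0].mean()
        inside_b = bwd[0, 14:26, 14:26, 0].mean()
        assert inside_f == pytest.approx(-inside_b, rel=0.25)

    def test_output_shape_contract(self):
        frames = np.random.default_rng(0).random((6, 24, 24))
        assert compute_flow(frames).shape == (5, 24, 24, 2)

    def test_single_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_flow(np.zeros((1, 16, 16)))


class TestLoadSample:
    @pytest.fixture
    def clip_on_disk(self, tmp_path):
        import imageio.v3 as iio

        rng = np.random.default_rng(5)
        clip = tmp_path / "walking" / "walking_000"
        clip.mkdir(parents=True)
        for t in range(12):
            img = (rng.random((32, 32, 3)) * 255).astype(np.uint8)
            iio.imwrite(clip / f"frame_{t:04d}.png", img)
        record = ClipRecord(path=str(clip), label="walking", num_frames=12, fps=8)
        manifest = DatasetManifest(records=[record], classes=["walking"])
        return record, manifest

    def test_rgb_values_in_unit_interval(self, clip_on_disk):
        record, manifest = clip_on_disk
        cfg = IOConfig(height=32, width=32, flow_depth=3)
        s = load_sample(record, cfg, manifest)
        assert s.rgb_stack.min() >= 0.0 and s.rgb_stack.max() <= 1.0
        assert s.flow_stack.shape == (3, 32, 32, 2)
        assert s.label_index == 0

    def test_flow_cache_fidelity(self, clip_on_disk, tmp_path):
        record, manifest = clip_on_disk
        cold = IOConfig(height=32, width=32, flow_depth=3,
                        cache_dir=str(tmp_path / "cache"))
        first = load_sample(record, cold, manifest)
        second = load_sample(record, cold, manifest)  # served from cache
        np.testing.assert_array_equal(first.flow_stack, second.flow_stack)
        fresh = load_sample(record, IOConfig(height=32, width=32, flow_depth=3),
                            manifest)
        np.testing.assert_array_equal(first.flow_stack, fresh.flow_stack)

    def test_split_arrays_channel_layout(self, clip_on_disk):
        record, manifest = clip_on_disk
        cfg = IOConfig(height=32, width=32, flow_depth=3)
        x_rgb, x_flow, y = load_split_arrays(manifest, "train", cfg)
        assert x_rgb.shape == (1, 32, 32, 3)
        assert x_flow.shape == (1, 32, 32, 6)
        np.testing.assert_array_equal(y, [0])
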