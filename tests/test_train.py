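"""Training loop behavior on small in-memory problems.

These tests use tiny inputs (8x8) and a linearly separable three-class
signal so each run takes well under a second; the full-benchmark
phenomena are exercised separately in the acceptance suite.
"""

import numpy as np
import pytest

from tsml import (BackboneSpec, ConfigurationError, StreamPair, TSMLModel,
                  TrainConfig, train_single, train_stream, train_tsml)
from tsml.backbones import build_backbone
from tsml.rng import spawn_seed


def toy_data(n_per_class=12, C=3, hw=8, cin=3, seed=0):
    """Class k has mean intensity k/(C-1) in channel 0: separable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for k in range(C):
        x = rng.normal(0, 0.3, size=(n_per_class, hw, hw, cin))
        x[..., 0] += 2.0 * k / (C - 1) - 1.0
        xs.append(x)
        ys.append(np.full(n_per_class, k))
    return (np.concatenate(xs).astype(np.float32),
            np.concatenate(ys).astype(np.int64))


def build_pair(seed=0, cin=3, C=3):
    spec = BackboneSpec("tiny", cin, C)
    return StreamPair.build("spatial", spec, spec, seed)


def params_of(net):
    return [p.value.copy() for p in net.params()]


CFG = dict(batch_size=16, learning_rate=0.01, epochs=4, seed=3)


class TestMutualReduction:
    def test_kl_weight_zero_matches_independent_training_bitwise(self):
        """With the KL coupling off, each student's trajectory equals an
        independent cross-entropy training of the same network."""
        data = toy_data()
        cfg = TrainConfig(mutual=True, kl_weight=0.0, alpha=0.5, **CFG)
        pair = build_pair(seed=9)
        init1 = build_backbone(pair.spec1, spawn_seed(9, "spatial", "student1"))
        init2 = build_backbone(pair.spec2, spawn_seed(9, "spatial", "student2"))
        train_stream(pair, data, cfg)

        cfg_single = TrainConfig(mutual=False, alpha=0.5, **CFG)
        train_single(init1, data, cfg_single, "spatial", loss_scale=1.0)
        train_single(init2, data, cfg_single, "spatial", loss_scale=1.0)
        for a, b in zip(params_of(pair.student1), params_of(init1)):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(params_of(pair.student2), params_of(init2)):
            np.testing.assert_array_equal(a, b)

    def test_mutual_false_equals_kl_weight_zero(self):
        data = toy_data()
        p1 = build_pair(seed=4)
        p2 = build_pair(seed=4)
        train_stream(p1, data, TrainConfig(mutual=False, **CFG))
        train_stream(p2, data, TrainConfig(mutual=True, kl_weight=0.0, **CFG))
        for a, b in zip(params_of(p1.student1), params_of(p2.student1)):
            np.testing.assert_array_equal(a, b)


class TestAlphaBoundaries:
    def test_alpha_zero_freezes_student2(self):
        data = toy_data()
        pair = build_pair(seed=1)
        before = params_of(pair.student2)
        train_stream(pair, data, TrainConfig(alpha=0.0, **CFG))
        after = params_of(pair.student2)
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)
        # student1 did move
        moved = build_backbone(pair.spec1, spawn_seed(1, "spatial", "student1"))
        assert any(
            not np.array_equal(a, b.value)
            for a, b in zip(params_of(pair.student1), moved.params())
        )

    def test_alpha_one_freezes_student1(self):
        data = toy_data()
        pair = build_pair(seed=1)
        before = params_of(pair.student1)
        train_stream(pair, data, TrainConfig(alpha=1.0, **CFG))
        for a, b in zip(before, params_of(pair.student1)):
            np.testing.assert_array_equal(a, b)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(alpha=1.2)


class TestTrainingDynamics:
    def test_supervised_loss_decreases_on_separable_data(self):
        data = toy_data()
        pair = build_pair(seed=2)
        log = train_stream(pair, data, TrainConfig(**CFG))
        assert log.records[-1].ce1 < log.records[0].ce1
        assert log.records[-1].ce2 < log.records[0].ce2
        assert all(np.isfinite(r.stream_loss) for r in log.records)

    def test_one_record_per_epoch_with_expected_fields(self):
        data = toy_data()
        pair = build_pair(seed=2)
        log = train_stream(pair, data, TrainConfig(**CFG), test_data=data)
        assert len(log.records) == CFG["epochs"]
        assert log.records[0].acc1_test is not None
        df = log.to_dataframe()
        assert {"stream_loss", "ce1", "kl1", "acc1_train"} <= set(df.columns)

    def test_bitwise_deterministic_given_seed(self):
        data = toy_data()
        a, b = build_pair(seed=6), build_pair(seed=6)
        train_stream(a, data, TrainConfig(**CFG))
        train_stream(b, data, TrainConfig(**CFG))
        for pa, pb in zip(params_of(a.student1), params_of(b.student1)):
            np.testing.assert_array_equal(pa, pb)

    def test_alternating_scheme_differs_from_simultaneous(self):
        data = toy_data()
        a, b = build_pair(seed=6), build_pair(seed=6)
        train_stream(a, data, TrainConfig(update_scheme="simultaneous", **CFG))
        train_stream(b, data, TrainConfig(update_scheme="alternating", **CFG))
        assert any(
            not np.array_equal(pa, pb)
            for pa, pb in zip(params_of(a.student2), params_of(b.student2))
        )

    def test_channel_mismatch_rejected(self):
        x, y = toy_data(cin=5)
        pair = build_pair(cin=3)
        with pytest.raises(Exception):
            train_stream(pair, (x, y), TrainConfig(**CFG))


class TestTrainTSML:
    def test_both_streams_trained_and_logged(self, tmp_path):
        x_rgb, y = toy_data(cin=3, seed=0)
        x_flow, _ = toy_data(cin=6, seed=1)
        spec_r = BackboneSpec("tiny", 3, 3)
        spec_f = BackboneSpec("tiny", 6, 3)
        model = TSMLModel(
            spatial=StreamPair.build("spatial", spec_r, spec_r, 0),
            temporal=StreamPair.build("temporal", spec_f, spec_f, 0),
        )
        cfg = TrainConfig(**CFG)
        logs = train_tsml(model, (x_rgb, x_flow, y), cfg,
                          checkpoint_dir=tmp_path, log_path=tmp_path / "log.jsonl")
        assert set(logs) == {"spatial", "temporal"}
        assert len(logs["spatial"].records) == cfg.epochs
        assert (tmp_path / "spatial_student1.npz").exists()
        assert (tmp_path / "log.jsonl").read_text().count("\n") == 2 * cfg.epochs
        # training accuracy beats chance on separable data
        assert logs["spatial"].records[-1].acc1_train > 100.0 / 3
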