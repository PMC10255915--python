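"""Mutual-learning training loops.

Each stream trains its two students jointly: per batch, both students
run forward, each student's loss is its cross-entropy plus a KL term
toward the peer's (detached) posterior, and the stream loss

    L_stream = (1 - alpha) * L_1 + alpha * L_2

is minimized by gradient descent with momentum.  Because the peer enters
each student's loss only as a constant, the combined update decomposes:
student 1's parameters receive a 2(1 - alpha)-weighted gradient of L_1
and student 2's a 2*alpha-weighted gradient of L_2 (the factor 2 makes
the default alpha = 0.5 equivalent to the classic collaborative
objective L_1 + L_2, so a mutual student and an independently trained
network see the same effective step size).  At alpha = 0 the second
student receives no gradient at all and stays frozen.

The default ``simultaneous`` scheme performs both updates from the same
pre-update forward passes; ``alternating`` updates student 1 first and
recomputes its posterior before updating student 2 (the original deep
mutual learning recipe).  With the KL weight at 0, mutual training is
exactly two decoupled cross-entropy trainings, up to the constant alpha
weights on the gradients; :func:`train_single` exposes ``loss_scale`` so
that equivalence can be checked bitwise.

Shuffling is seeded per (seed, modality, epoch) and is independent of
the number of students, so single and mutual runs see identical batch
orders.  No learning-rate schedule or early stopping is applied: the
fixed-rate recipe (momentum 0.9, batch 16, lr 0.001, alpha 0.5) is kept
and test-scale runs shorten only the epoch count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, TSMLError
from .losses import EPS, KL_DIRECTIONS, kl_divergence, softmax_probs
from .model import StreamPair, TSMLModel, save_stream_pair
from .nn import SGD, Sequential
from .rng import substream

__all__ = ["TrainConfig", "EpochRecord", "TrainLog", "train_stream",
           "train_single", "train_tsml"]

logger = logging.getLogger(__name__)

UPDATE_SCHEMES = ("simultaneous", "alternating")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults follow the fixed recipe."""

    momentum: float = 0.9
    batch_size: int = 16
    learning_rate: float = 0.001
    alpha: float = 0.5
    epochs: int = 500
    seed: int = 0
    kl_direction: str = "peer_to_self"
    kl_weight: float = 1.0
    mutual: bool = True
    update_scheme: str = "simultaneous"
    backbones: tuple[str, str] = ("tiny", "tiny")

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.kl_direction not in KL_DIRECTIONS:
            raise ConfigurationError(f"kl_direction must be one of {KL_DIRECTIONS}")
        if self.update_scheme not in UPDATE_SCHEMES:
            raise ConfigurationError(f"update_scheme must be one of {UPDATE_SCHEMES}")
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class EpochRecord:
    epoch: int
    stream_loss: float
    ce1: float
    kl1: float
    acc1_train: float
    ce2: float | None = None
    kl2: float | None = None
    acc2_train: float | None = None
    acc1_test: float | None = None
    acc2_test: float | None = None


@dataclass
class TrainLog:
    modality: str
    records: list[EpochRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def append_jsonl(self, path: str | Path) -> None:
        with open(path, "a") as fh:
            for r in self.records:
                fh.write(json.dumps({"modality": self.modality, **asdict(r)}) + "\n")


# ---------------------------------------------------------------------------
# closed-form logit gradients (batch mean, peer detached)

def _grad_logits(p: np.ndarray, y: np.ndarray, p_peer: np.ndarray | None,
                 kl_direction: str, kl_weight: float) -> np.ndarray:
    n, C = p.shape
    g = p.copy()
    g[np.arange(n), y] -= 1.0  # d(CE)/dz
    if p_peer is not None and kl_weight != 0.0:
        if kl_direction == "peer_to_self":
            g += kl_weight * (p - p_peer)
        else:
            r = np.log(np.clip(p, EPS, 1.0)) - np.log(np.clip(p_peer, EPS, 1.0))
            g += kl_weight * p * (r - np.sum(p * r, axis=1, keepdims=True))
    return g / n


def _batch_ce(p: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(p[np.arange(len(y)), y], EPS, 1.0)).mean())


def _check_data(x: np.ndarray, y: np.ndarray, net: Sequential, what: str) -> None:
    if x.ndim != 4 or x.shape[3] != net.in_channels:
        raise InvalidInputError(
            f"{what}: input channels {x.shape[3] if x.ndim == 4 else '?'} "
            f"do not match network ({net.in_channels})"
        )
    if len(x) != len(y):
        raise InvalidInputError(f"{what}: {len(x)} inputs vs {len(y)} labels")


def _test_accuracy(net: Sequential, test_data) -> float:
    x, y = test_data
    correct = 0
    for i in range(0, len(x), 64):
        logits = net.forward(x[i : i + 64])
        correct += int(np.sum(np.argmax(logits, axis=1) == y[i : i + 64]))
    return 100.0 * correct / len(y)


def _epoch_batches(n: int, batch_size: int, seed: int, modality: str, epoch: int):
    order = substream(seed, "shuffle", modality, epoch).permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_stream(pair: StreamPair, data, config: TrainConfig,
                 test_data=None, start_epoch: int = 0,
                 optimizers: tuple[SGD, SGD] | None = None) -> TrainLog:
    """Train both students of one stream; returns the per-epoch log.

    ``data`` (and optional ``test_data``) are ``(x, y)`` with NHWC input
    stacks matching the pair's modality.  With ``config.mutual`` False
    the KL coupling is off and the two students train as independent
    cross-entropy classifiers on identical batches.
    """
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    _check_data(x, y, pair.student1, f"{pair.modality} stream")
    _check_data(x, y, pair.student2, f"{pair.modality} stream")

    kl_w = config.kl_weight if config.mutual else 0.0
    opt1, opt2 = optimizers or (
        SGD(pair.student1, config.learning_rate, config.momentum),
        SGD(pair.student2, config.learning_rate, config.momentum),
    )
    # Per-student gradient weights 2(1-alpha) and 2*alpha: the optimized
    # objective is 2*L_stream, so at the default alpha = 0.5 each student
    # trains at the standard rate (the classic collaborative L_1 + L_2
    # objective) and at the boundaries one student is exactly frozen.
    scale1, scale2 = 2.0 * (1.0 - config.alpha), 2.0 * config.alpha
    log = TrainLog(modality=pair.modality)

    for epoch in range(start_epoch, config.epochs):
        sums = np.zeros(5)  # stream loss, ce1, kl1, ce2, kl2
        correct = np.zeros(2)
        nbatch = 0
        for idx in _epoch_batches(len(x), config.batch_size, config.seed,
                                  pair.modality, epoch):
            xb, yb = x[idx], y[idx]
            z1 = pair.student1.forward(xb)
            p1 = softmax_probs(z1)
            z2 = pair.student2.forward(xb)
            p2 = softmax_probs(z2)

            ce1, ce2 = _batch_ce(p1, yb), _batch_ce(p2, yb)
            kl1 = kl_divergence(p2, p1, check=False) if kl_w else 0.0
            kl2 = kl_divergence(p1, p2, check=False) if kl_w else 0.0
            # logged on the (1-alpha)/alpha scale; the optimizer uses 2x
            l_stream = (1.0 - config.alpha) * (ce1 + kl_w * kl1) \
                + config.alpha * (ce2 + kl_w * kl2)
            if not np.isfinite(l_stream):
                raise TSMLError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {nbatch} of the {pair.modality} stream"
                )
            sums += (l_stream, ce1, kl_w * kl1, ce2, kl_w * kl2)
            correct += (
                np.sum(np.argmax(p1, axis=1) == yb),
                np.sum(np.argmax(p2, axis=1) == yb),
            )
            nbatch += 1

            if scale1 != 0.0:
                g1 = scale1 * _grad_logits(p1, yb, p2, config.kl_direction, kl_w)
                pair.student1.zero_grad()
                pair.student1.backward(g1.astype(np.float32))
                opt1.step()
            if scale2 != 0.0:
                if config.update_scheme == "alternating" and kl_w and scale1 != 0.0:
                    # refresh the peer posterior after student 1's update
                    p1 = softmax_probs(pair.student1.forward(xb))
                g2 = scale2 * _grad_logits(p2, yb, p1, config.kl_direction, kl_w)
                pair.student2.zero_grad()
                pair.student2.backward(g2.astype(np.float32))
                opt2.step()

        rec = EpochRecord(
            epoch=epoch,
            stream_loss=sums[0] / nbatch,
            ce1=sums[1] / nbatch,
            kl1=sums[2] / nbatch,
            acc1_train=100.0 * correct[0] / len(y),
            ce2=sums[3] / nbatch,
            kl2=sums[4] / nbatch,
            acc2_train=100.0 * correct[1] / len(y),
        )
        if test_data is not None:
            rec.acc1_test = _test_accuracy(pair.student1, test_data)
            rec.acc2_test = _test_accuracy(pair.student2, test_data)
        log.records.append(rec)
    return log


def train_single(net: Sequential, data, config: TrainConfig, modality: str,
                 test_data=None, loss_scale: float = 1.0) -> TrainLog:
    """Plain cross-entropy training of one network (the Sig baselines).

    Uses the same seeded shuffle stream as :func:`train_stream`, so a
    single run and a decoupled mutual run see identical batches.
    ``loss_scale`` multiplies the gradient by a constant, mirroring the
    alpha weight a student carries inside a stream loss.
    """
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    _check_data(x, y, net, f"{modality} single")
    opt = SGD(net, config.learning_rate, config.momentum)
    log = TrainLog(modality=modality)
    for epoch in range(config.epochs):
        loss_sum, correct, nbatch = 0.0, 0, 0
        for idx in _epoch_batches(len(x), config.batch_size, config.seed,
                                  modality, epoch):
            xb, yb = x[idx], y[idx]
            p = softmax_probs(net.forward(xb))
            ce = _batch_ce(p, yb)
            if not np.isfinite(ce):
                raise TSMLError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {nbatch} ({modality} single)"
                )
            loss_sum += ce
            correct += int(np.sum(np.argmax(p, axis=1) == yb))
            nbatch += 1
            g = loss_scale * _grad_logits(p, yb, None, config.kl_direction, 0.0)
            net.zero_grad()
            net.backward(g.astype(np.float32))
            opt.step()
        rec = EpochRecord(
            epoch=epoch,
            stream_loss=loss_scale * loss_sum / nbatch,
            ce1=loss_sum / nbatch,
            kl1=0.0,
            acc1_train=100.0 * correct / len(y),
        )
        if test_data is not None:
            rec.acc1_test = _test_accuracy(net, test_data)
        log.records.append(rec)
    return log


def train_tsml(model: TSMLModel, train_data, config: TrainConfig,
               test_data=None, checkpoint_dir: str | Path | None = None,
               log_path: str | Path | None = None) -> dict[str, TrainLog]:
    """Train both streams independently; fusion happens only at evaluation.

    ``train_data``/``test_data`` are ``(x_rgb, x_flow, y)`` triples.
    Returns ``{"spatial": log, "temporal": log}``.
    """
    x_rgb, x_flow, y = train_data
    test_rgb = test_flow = None
    if test_data is not None:
        t_rgb, t_flow, t_y = test_data
        test_rgb, test_flow = (t_rgb, t_y), (t_flow, t_y)
    logs = {}
    for pair, x, tdata in (
        (model.spatial, x_rgb, test_rgb),
        (model.temporal, x_flow, test_flow),
    ):
        logs[pair.modality] = train_stream(pair, (x, y), config, test_data=tdata)
        if checkpoint_dir is not None:
            save_stream_pair(pair, Path(checkpoint_dir), epoch=config.epochs,
                             seed=config.seed)
        if log_path is not None:
            logs[pair.modality].append_jsonl(log_path)
    return logs
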