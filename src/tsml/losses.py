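"""Loss mathematics for deep mutual learning.

Each stream of the two-stream classifier trains two peer "student"
networks.  Student *k* minimizes a supervised cross-entropy term plus a
KL-divergence term that pulls its predictive distribution toward its
peer's posterior:

    L_k      = CE(p_k, y) + D_KL(p_peer || p_k)
    L_stream = (1 - alpha) * L_1 + alpha * L_2

with ``alpha`` in [0, 1] balancing the two students.  All logarithms are
natural (losses in nats).  Batch inputs reduce by the mean over samples,
so loss magnitudes are batch-size invariant.

The functions here are pure NumPy and are shared by the trainer and the
test oracles.  Probabilities are clamped to [1e-12, 1] inside logs so
degenerate one-hot predictions yield finite losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "EPS",
    "KL_DIRECTIONS",
    "softmax_probs",
    "cross_entropy",
    "kl_divergence",
    "student_loss",
    "stream_loss",
    "mutual_stream_loss",
    "StudentLoss",
    "LossBreakdown",
]

logger = logging.getLogger(__name__)

#: Clamp applied to probabilities inside logarithms.
EPS = 1e-12

#: Allowed orientations of the mutual-learning KL term.  ``peer_to_self``
#: is D_KL(p_peer || p_self), the standard deep-mutual-learning form.
KL_DIRECTIONS = ("peer_to_self", "self_to_peer")


def _as_float_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim not in (1, 2):
        raise InvalidInputError(f"{name} must be 1-D or 2-D, got shape {a.shape}")
    return a


def _check_probs(p: np.ndarray, name: str, tol: float = 1e-6) -> None:
    if not np.all(np.isfinite(p)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    if np.any(p < 0):
        raise InvalidInputError(f"{name} contains negative entries")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol):
        raise InvalidInputError(
            f"{name} rows must sum to 1 (max deviation {np.max(np.abs(sums - 1.0)):.2e})"
        )


def softmax_probs(logits) -> np.ndarray:
    """Softmax over the last axis, stabilized by max subtraction.

    Accepts a single logit vector or a batch of them; the class axis must
    have length >= 2.  Raises :class:`InvalidInputError` on non-finite
    logits.
    """
    z = _as_float_array(logits, "logits")
    if z.shape[-1] < 2:
        raise InvalidInputError("need at least 2 classes")
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("logits contain non-finite entries")
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(p, y, *, check: bool = True) -> float:
    """Cross-entropy -log p[y] in nats; mean over the batch for 2-D input.

    ``y`` is an integer class index (or an array of them for a batch).
    A zero probability at the true class is clamped to 1e-12 and logged,
    never infinite.
    """
    pa = _as_float_array(p, "p")
    if check:
        _check_probs(pa, "p")
    ya = np.asarray(y, dtype=np.int64)
    if pa.ndim == 1:
        pa = pa[None, :]
        ya = ya.reshape(1)
    C = pa.shape[-1]
    if np.any(ya < 0) or np.any(ya >= C):
        raise InvalidInputError(f"class index out of range [0, {C})")
    picked = pa[np.arange(pa.shape[0]), ya]
    if np.any(picked < EPS):
        logger.warning(
            "cross_entropy: %d true-class probabilities below %.0e were clamped",
            int(np.sum(picked < EPS)),
            EPS,
        )
    return float(-np.log(np.clip(picked, EPS, 1.0)).mean())


def kl_divergence(p_ref, p_target, *, check: bool = True) -> float:
    """D_KL(p_ref || p_target) = sum_c p_ref_c log(p_ref_c / p_target_c).

    Both arguments are clamped to [1e-12, 1] before the log.  For 2-D
    inputs the mean over rows is returned.  The divergence is >= 0 and 0
    iff the distributions coincide (Gibbs' inequality).
    """
    a = _as_float_array(p_ref, "p_ref")
    b = _as_float_array(p_target, "p_target")
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    if check:
        _check_probs(a, "p_ref")
        _check_probs(b, "p_target")
    ac = np.clip(a, EPS, 1.0)
    bc = np.clip(b, EPS, 1.0)
    per_row = np.sum(ac * (np.log(ac) - np.log(bc)), axis=-1)
    return float(max(per_row.mean(), 0.0))


@dataclass(frozen=True)
class StudentLoss:
    """Loss of one student: supervised CE, mutual KL, and their sum."""

    ce: float
    kl: float

    @property
    def total(self) -> float:
        return self.ce + self.kl


def student_loss(
    p_self,
    p_peer,
    y,
    *,
    kl_direction: str = "peer_to_self",
    kl_weight: float = 1.0,
) -> StudentLoss:
    """One student's loss: CE(p_self, y) + kl_weight * KL term.

    ``kl_direction`` selects D_KL(peer||self) (default) or
    D_KL(self||peer).  The peer distribution is treated as a constant:
    no gradient flows into the peer through this term (the trainer
    enforces that; here the function is pure).  ``kl_weight`` exists so
    that setting it to 0 reduces the loss to plain cross-entropy exactly.
    """
    if kl_direction not in KL_DIRECTIONS:
        raise ConfigurationError(
            f"kl_direction must be one of {KL_DIRECTIONS}, got {kl_direction!r}"
        )
    ce = cross_entropy(p_self, y)
    if kl_weight == 0.0:
        kl = 0.0
    elif kl_direction == "peer_to_self":
        kl = kl_weight * kl_divergence(p_peer, p_self)
    else:
        kl = kl_weight * kl_divergence(p_self, p_peer)
    return StudentLoss(ce=ce, kl=kl)


def stream_loss(l1: float, l2: float, alpha: float) -> float:
    """Convex combination (1 - alpha) * l1 + alpha * l2 of the two students."""
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha == 0.0:
        return float(l1)
    if alpha == 1.0:
        return float(l2)
    return float((1.0 - alpha) * l1 + alpha * l2)


@dataclass(frozen=True)
class LossBreakdown:
    """Full per-stream loss decomposition for logging and tests."""

    student1: StudentLoss
    student2: StudentLoss
    alpha: float

    @property
    def stream(self) -> float:
        return stream_loss(self.student1.total, self.student2.total, self.alpha)


def mutual_stream_loss(
    p1,
    p2,
    y,
    *,
    alpha: float = 0.5,
    kl_direction: str = "peer_to_self",
    kl_weight: float = 1.0,
) -> LossBreakdown:
    """Both students' losses and their alpha-weighted stream loss."""
    s1 = student_loss(p1, p2, y, kl_direction=kl_direction, kl_weight=kl_weight)
    s2 = student_loss(p2, p1, y, kl_direction=kl_direction, kl_weight=kl_weight)
    if not (0.0 <= alpha <= 1.0):
        raise ConfigurationError(f"alpha must lie in [0, 1], got {alpha}")
    return LossBreakdown(student1=s1, student2=s2, alpha=alpha)
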