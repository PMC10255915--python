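"""Late fusion, accuracy/confusion metrics, and results tables.

The two streams are fused at decision level: the spatial (RGB) and
temporal (flow) softmax vectors are combined as the convex combination

    p_fused = w_rgb * p_rgb + (1 - w_rgb) * p_flow

and the fused class is the argmax, ties broken toward the lowest class
index.  Accuracies are reported in percent; results tables follow the
``Model / Flow (%) / RGB (%) / Two-Stream Fusion (%)`` schema with
two-decimal rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "FusionConfig",
    "EvalReport",
    "fuse",
    "accuracy_percent",
    "confusion_matrix",
    "evaluate",
    "evaluate_all",
    "results_table",
]

_PAIRINGS = ("by_index", "best_of")


@dataclass(frozen=True)
class FusionConfig:
    """Stream fusion weight and the rule pairing students across streams.

    ``by_index`` fuses spatial student k with temporal student k;
    ``best_of`` fuses, per stream, the student with the higher
    single-stream accuracy on the evaluation data.
    """

    w_rgb: float = 0.5
    student_pairing: str = "by_index"

    def __post_init__(self):
        if not (0.0 <= self.w_rgb <= 1.0):
            raise ConfigurationError(f"w_rgb must lie in [0, 1], got {self.w_rgb}")
        if self.student_pairing not in _PAIRINGS:
            raise ConfigurationError(
                f"student_pairing must be one of {_PAIRINGS}"
            )


@dataclass
class EvalReport:
    """Per-stream and fused test metrics plus efficiency counters."""

    accuracy_flow: float
    accuracy_rgb: float
    accuracy_fused: float
    confusion: np.ndarray  # (C, C), rows = true class, cols = fused prediction
    params: int = 0
    flops: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy_flow": self.accuracy_flow,
            "accuracy_rgb": self.accuracy_rgb,
            "accuracy_fused": self.accuracy_fused,
            "confusion": self.confusion.tolist(),
            "params": self.params,
            "flops": self.flops,
        }


def fuse(p_rgb: np.ndarray, p_flow: np.ndarray, fusion: FusionConfig) -> np.ndarray:
    """Convex combination of the two streams' class probabilities."""
    a = np.asarray(p_rgb, dtype=np.float64)
    b = np.asarray(p_flow, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return fusion.w_rgb * a + (1.0 - fusion.w_rgb) * b


def _predict(p: np.ndarray) -> np.ndarray:
    # np.argmax returns the first (lowest) index on ties.
    return np.argmax(p, axis=-1)


def accuracy_percent(p: np.ndarray, y: np.ndarray) -> float:
    return float(100.0 * np.mean(_predict(p) == np.asarray(y)))


def confusion_matrix(p: np.ndarray, y: np.ndarray, num_classes: int) -> np.ndarray:
    pred = _predict(p)
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (np.asarray(y, dtype=np.int64), pred), 1)
    return cm


def _batched_probs(net, x: np.ndarray, batch: int = 64) -> np.ndarray:
    from .losses import softmax_probs

    out = []
    for i in range(0, x.shape[0], batch):
        out.append(softmax_probs(net.forward(x[i : i + batch])))
    return np.concatenate(out, axis=0)


def evaluate(model, test_data, fusion: FusionConfig | None = None,
             student_index: int = 1) -> EvalReport:
    """Evaluate one fused predictor of a trained two-stream model.

    ``test_data`` is ``(x_rgb, x_flow, y)`` with NHWC stacks.  Under
    ``by_index`` pairing, spatial and temporal students number
    ``student_index`` are fused; under ``best_of`` the per-stream
    student with the higher single-stream accuracy is chosen.
    """
    fusion = fusion or model.fusion
    x_rgb, x_flow, y = test_data
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise InvalidInputError("empty test set")
    C = model.num_classes

    rgb_probs = [_batched_probs(s, x_rgb) for s in model.spatial.students]
    flow_probs = [_batched_probs(s, x_flow) for s in model.temporal.students]

    if fusion.student_pairing == "best_of":
        i_rgb = int(np.argmax([accuracy_percent(p, y) for p in rgb_probs]))
        i_flow = int(np.argmax([accuracy_percent(p, y) for p in flow_probs]))
    else:
        if student_index not in (1, 2):
            raise ConfigurationError("student_index must be 1 or 2")
        i_rgb = i_flow = student_index - 1

    p_rgb, p_flow = rgb_probs[i_rgb], flow_probs[i_flow]
    p_fused = fuse(p_rgb, p_flow, fusion)

    from .backbones import count_flops, count_params

    nets = [model.spatial.students[i_rgb], model.temporal.students[i_flow]]
    shapes = [x_rgb.shape[1:], x_flow.shape[1:]]
    return EvalReport(
        accuracy_flow=accuracy_percent(p_flow, y),
        accuracy_rgb=accuracy_percent(p_rgb, y),
        accuracy_fused=accuracy_percent(p_fused, y),
        confusion=confusion_matrix(p_fused, y, C),
        params=sum(count_params(n) for n in nets),
        flops=sum(count_flops(n, s) for n, s in zip(nets, shapes)),
    )


def evaluate_all(model, test_data, fusion: FusionConfig | None = None
                 ) -> dict[int, EvalReport]:
    """By-index reports for both student pairings (the "-1"/"-2" rows)."""
    return {
        k: evaluate(model, test_data, fusion, student_index=k) for k in (1, 2)
    }


def results_table(reports: list[tuple[str, EvalReport]],
                  path: str | Path | None = None) -> pd.DataFrame:
    """Labeled reports as a results table, optionally written to CSV.

    Percentages are rounded to two decimals; rows keep input order.
    """
    rows = [
        {
            "Model": label,
            "Flow (%)": round(r.accuracy_flow, 2),
            "RGB (%)": round(r.accuracy_rgb, 2),
            "Two-Stream Fusion (%)": round(r.accuracy_fused, 2),
        }
        for label, r in reports
    ]
    df = pd.DataFrame(rows, columns=["Model", "Flow (%)", "RGB (%)",
                                     "Two-Stream Fusion (%)"])
    if path is not None:
        df.to_csv(path, index=False, float_format="%.2f")
    return df
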