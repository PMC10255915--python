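"""Experiment matrix: single baselines versus mutual pairs per backbone.

Row labels follow the field's convention: ``SigRes18`` is a two-stream
model with a single network per stream; ``MulRes18(Res34)`` is the
Res18-backed student trained alongside a Res34 peer; ``-1``/``-2``
suffixes index the two students of a same-backbone mutual pair.  Here
the registry names are the tiny family, so rows read e.g. ``SigTiny``
or ``MulTiny(TinyWide)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backbones import BackboneSpec
from .data import IOConfig
from .errors import ConfigurationError
from .evaluation import (EvalReport, FusionConfig, accuracy_percent,
                         confusion_matrix, evaluate_all, fuse, results_table)
from .losses import softmax_probs
from .model import StreamPair, TSMLModel
from .rng import spawn_seed
from .synthetic import GeneratorConfig, make_benchmark_data
from .train import TrainConfig, train_single, train_tsml

__all__ = ["ExperimentCell", "model_label", "run_experiment_matrix",
           "run_benchmark"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentCell:
    """One grid cell: a backbone (pair) with or without mutual learning."""

    backbone1: str
    backbone2: str | None = None  # None -> single-network baseline
    mutual: bool = True

    def __post_init__(self):
        if self.mutual and self.backbone2 is None:
            raise ConfigurationError("a mutual cell needs two backbone names")
        if not self.mutual and self.backbone2 is not None:
            raise ConfigurationError("a single cell takes one backbone name")


def _display(name: str) -> str:
    return "".join(part.capitalize() for part in name.split("_"))


def model_label(backbone1: str, backbone2: str | None = None,
                index: int | None = None) -> str:
    """Row label: Sig<A>, Mul<A>(<B>), or Mul<A>(<A>)-i."""
    if backbone2 is None:
        return f"Sig{_display(backbone1)}"
    label = f"Mul{_display(backbone1)}({_display(backbone2)})"
    return f"{label}-{index}" if index is not None else label


def _probs(net, x, batch=64):
    return np.concatenate(
        [softmax_probs(net.forward(x[i:i + batch])) for i in range(0, len(x), batch)]
    )


def _report(rgb_net, flow_net, test_data, fusion: FusionConfig) -> EvalReport:
    x_rgb, x_flow, y = test_data
    p_rgb, p_flow = _probs(rgb_net, x_rgb), _probs(flow_net, x_flow)
    p_fused = fuse(p_rgb, p_flow, fusion)
    C = p_rgb.shape[1]
    return EvalReport(
        accuracy_flow=accuracy_percent(p_flow, y),
        accuracy_rgb=accuracy_percent(p_rgb, y),
        accuracy_fused=accuracy_percent(p_fused, y),
        confusion=confusion_matrix(p_fused, y, C),
    )


def run_experiment_matrix(cells, train_data, test_data, config: TrainConfig,
                          num_classes: int, fusion: FusionConfig | None = None,
                          out_csv: str | Path | None = None) -> pd.DataFrame:
    """Train and evaluate every cell; returns the accumulated table.

    ``train_data``/``test_data`` are ``(x_rgb, x_flow, y)`` triples
    shared by all cells.  After each completed cell the partial table is
    rewritten to ``out_csv``, so an interrupted grid keeps its finished
    rows.
    """
    fusion = fusion or FusionConfig()
    x_rgb, x_flow, _ = train_data
    c_rgb, c_flow = x_rgb.shape[3], x_flow.shape[3]
    rows: list[tuple[str, EvalReport]] = []

    for cell in cells:
        if not cell.mutual:
            spec_rgb = BackboneSpec(cell.backbone1, c_rgb, num_classes)
            spec_flow = BackboneSpec(cell.backbone1, c_flow, num_classes)
            from .backbones import build_backbone

            rgb_net = build_backbone(
                spec_rgb, spawn_seed(config.seed, "spatial", "student1"))
            flow_net = build_backbone(
                spec_flow, spawn_seed(config.seed, "temporal", "student1"))
            train_single(rgb_net, (x_rgb, train_data[2]), config, "spatial")
            train_single(flow_net, (x_flow, train_data[2]), config, "temporal")
            rows.append((model_label(cell.backbone1),
                         _report(rgb_net, flow_net, test_data, fusion)))
        else:
            spatial = StreamPair.build(
                "spatial",
                BackboneSpec(cell.backbone1, c_rgb, num_classes),
                BackboneSpec(cell.backbone2, c_rgb, num_classes),
                config.seed,
            )
            temporal = StreamPair.build(
                "temporal",
                BackboneSpec(cell.backbone1, c_flow, num_classes),
                BackboneSpec(cell.backbone2, c_flow, num_classes),
                config.seed,
            )
            model = TSMLModel(spatial=spatial, temporal=temporal, fusion=fusion)
            train_tsml(model, train_data, config)
            reports = evaluate_all(model, test_data, fusion)
            same = cell.backbone1 == cell.backbone2
            for k in (1, 2):
                first, second = (
                    (cell.backbone1, cell.backbone2)
                    if k == 1
                    else (cell.backbone2, cell.backbone1)
                )
                label = model_label(first, second, index=k if same else None)
                rows.append((label, reports[k]))
        if out_csv is not None:
            results_table(rows, out_csv)
        logger.info("experiment cell done: %s", rows[-1][0])

    return results_table(rows, out_csv)


def run_benchmark(seed: int, epochs: int = 30, backbone1: str = "tiny",
                  backbone2: str = "tiny",
                  gen_config: GeneratorConfig | None = None,
                  io_config: IOConfig | None = None,
                  fusion: FusionConfig | None = None) -> dict:
    """One full synthetic-benchmark comparison for one seed.

    Generates the benchmark (generator seed = ``seed``), trains the
    mutual two-stream model and the single-network baseline under the
    fixed recipe, and returns the test metrics both phenomena of
    interest are judged on:

    * ``single`` / ``mutual``: per-configuration accuracies (percent);
    * ``kl``: the per-epoch mean peer-KL of each stream's first student,
      whose first-to-last decrease measures the students converging
      toward each other.
    """
    gen = gen_config or GeneratorConfig(seed=seed)
    io = io_config or IOConfig()
    fusion = fusion or FusionConfig()
    train_data, test_data = make_benchmark_data(gen, io)
    x_rgb, x_flow, y = train_data
    K = gen.num_classes
    cfg = TrainConfig(epochs=epochs, seed=seed,
                      backbones=(backbone1, backbone2))

    # mutual two-stream model
    spatial = StreamPair.build(
        "spatial", BackboneSpec(backbone1, x_rgb.shape[3], K),
        BackboneSpec(backbone2, x_rgb.shape[3], K), seed)
    temporal = StreamPair.build(
        "temporal", BackboneSpec(backbone1, x_flow.shape[3], K),
        BackboneSpec(backbone2, x_flow.shape[3], K), seed)
    model = TSMLModel(spatial=spatial, temporal=temporal, fusion=fusion)
    logs = train_tsml(model, train_data, cfg)
    reports = evaluate_all(model, test_data, fusion)

    # single-network baseline (one student per stream, plain CE)
    from .backbones import build_backbone

    single_cfg = TrainConfig(epochs=epochs, seed=seed, mutual=False,
                             backbones=(backbone1, backbone1))
    rgb_net = build_backbone(BackboneSpec(backbone1, x_rgb.shape[3], K),
                             spawn_seed(seed, "spatial", "student1"))
    flow_net = build_backbone(BackboneSpec(backbone1, x_flow.shape[3], K),
                              spawn_seed(seed, "temporal", "student1"))
    train_single(rgb_net, (x_rgb, y), single_cfg, "spatial")
    train_single(flow_net, (x_flow, y), single_cfg, "temporal")
    single = _report(rgb_net, flow_net, test_data, fusion)

    kl = {
        mod: [r.kl1 for r in logs[mod].records]
        for mod in ("spatial", "temporal")
    }
    return {
        "seed": seed,
        "single": single.to_dict(),
        "mutual": {str(k): r.to_dict() for k, r in reports.items()},
        "mutual_fused_mean": float(
            np.mean([r.accuracy_fused for r in reports.values()])
        ),
        "kl": kl,
    }
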