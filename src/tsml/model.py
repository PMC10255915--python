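"""Two-stream, two-student model containers and checkpointing.

A :class:`StreamPair` holds the two peer student networks of one stream
(spatial = RGB appearance, temporal = stacked optical flow); a
:class:`TSMLModel` holds both streams plus the fusion configuration.
The students of a pair may share an architecture or differ, but they
never share parameter storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbones import BackboneSpec, build_backbone
from .errors import ConfigurationError, InvalidInputError
from .evaluation import FusionConfig
from .losses import softmax_probs
from .nn import Sequential
from .rng import spawn_seed

__all__ = [
    "StudentOutput",
    "StreamPair",
    "TSMLModel",
    "forward_stream",
    "save_stream_pair",
    "load_stream_pair",
]

MODALITIES = ("spatial", "temporal")


@dataclass(frozen=True)
class StudentOutput:
    """Logits and softmax probabilities of one student on one batch."""

    logits: np.ndarray  # (N, C)
    probs: np.ndarray  # (N, C), rows sum to 1


@dataclass
class StreamPair:
    """One stream's two mutually-learning students."""

    modality: str
    student1: Sequential
    student2: Sequential
    spec1: BackboneSpec
    spec2: BackboneSpec

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"modality must be one of {MODALITIES}")
        if self.spec1.num_classes != self.spec2.num_classes:
            raise ConfigurationError("students must share the class count")
        if self.student1 is self.student2:
            raise ConfigurationError("students must not share parameter storage")

    @property
    def num_classes(self) -> int:
        return self.spec1.num_classes

    @property
    def students(self) -> tuple[Sequential, Sequential]:
        return (self.student1, self.student2)

    @classmethod
    def build(
        cls,
        modality: str,
        spec1: BackboneSpec,
        spec2: BackboneSpec,
        seed: int,
    ) -> "StreamPair":
        """Build both students with independent seeded initializations."""
        s1 = build_backbone(spec1, spawn_seed(seed, modality, "student1"))
        s2 = build_backbone(spec2, spawn_seed(seed, modality, "student2"))
        return cls(modality, s1, s2, spec1, spec2)


@dataclass
class TSMLModel:
    """Spatial + temporal stream pairs with a late-fusion rule."""

    spatial: StreamPair
    temporal: StreamPair
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def __post_init__(self):
        if self.spatial.modality != "spatial" or self.temporal.modality != "temporal":
            raise ConfigurationError("streams assigned to the wrong modalities")
        if self.spatial.num_classes != self.temporal.num_classes:
            raise ConfigurationError("streams must share the class count")

    @property
    def num_classes(self) -> int:
        return self.spatial.num_classes


def _forward_student(net: Sequential, x: np.ndarray) -> StudentOutput:
    if x.ndim != 4 or x.shape[3] != net.in_channels:
        raise InvalidInputError(
            f"input has {x.shape[3] if x.ndim == 4 else '?'} channels, "
            f"network expects {net.in_channels}"
        )
    logits = net.forward(x.astype(np.float32, copy=False))
    return StudentOutput(logits=logits, probs=softmax_probs(logits))


def forward_stream(
    pair: StreamPair, batch: np.ndarray
) -> tuple[StudentOutput, StudentOutput]:
    """Run both students of a stream on the same NHWC batch."""
    return _forward_student(pair.student1, batch), _forward_student(
        pair.student2, batch
    )


def save_stream_pair(pair: StreamPair, out_dir: Path, *, epoch: int, seed: int,
                     optimizer_state: dict | None = None) -> None:
    """Write one .npz per student plus a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k, net in ((1, pair.student1), (2, pair.student2)):
        payload = dict(net.state_dict())
        if optimizer_state and k in optimizer_state:
            for i, v in enumerate(optimizer_state[k]):
                payload[f"__vel_{i}"] = v
        np.savez(out_dir / f"{pair.modality}_student{k}.npz", **payload)
    manifest = {
        "modality": pair.modality,
        "epoch": epoch,
        "seed": seed,
        "spec1": pair.spec1.__dict__,
        "spec2": pair.spec2.__dict__,
    }
    (out_dir / f"{pair.modality}_checkpoint.json").write_text(
        json.dumps(manifest, indent=2)
    )


def load_stream_pair(out_dir: Path, modality: str) -> tuple[StreamPair, int, dict]:
    """Load a saved pair; returns (pair, epoch, optimizer velocities)."""
    out_dir = Path(out_dir)
    man_path = out_dir / f"{modality}_checkpoint.json"
    if not man_path.exists():
        raise ConfigurationError(
            f"missing checkpoint manifest {man_path}; expected files: "
            f"{modality}_checkpoint.json, {modality}_student1.npz, "
            f"{modality}_student2.npz"
        )
    manifest = json.loads(man_path.read_text())
    spec1 = BackboneSpec(**manifest["spec1"])
    spec2 = BackboneSpec(**manifest["spec2"])
    pair = StreamPair.build(modality, spec1, spec2, manifest["seed"])
    velocities: dict[int, list[np.ndarray]] = {}
    for k, net in ((1, pair.student1), (2, pair.student2)):
        path = out_dir / f"{modality}_student{k}.npz"
        if not path.exists():
            raise ConfigurationError(f"missing checkpoint file {path}")
        with np.load(path) as data:
            weights = {n: data[n] for n in data.files if not n.startswith("__vel_")}
            vels = [data[n] for n in sorted(
                (f for f in data.files if f.startswith("__vel_")),
                key=lambda s: int(s.split("_")[-1]),
            )]
        net.load_state_dict(weights)
        if vels:
            velocities[k] = vels
    return pair, int(manifest["epoch"]), velocities
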