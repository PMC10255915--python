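"""Backbone registry and efficiency metrics (parameter and MAC counts).

The registry holds small CPU-trainable convolutional classifiers.  The
reference ``tiny`` backbone is three 3x3 conv blocks (8/16/32 channels,
each followed by ReLU and a stride-2 max pool), global average pooling
and a linear head; ``tiny_wide`` doubles the channel widths and
``tiny_deep`` adds a fourth block, giving a family of distinct
architectures for same-backbone versus different-backbone mutual
learning experiments.  New architectures can be added with
:func:`register_backbone`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import nn
from .errors import ConfigurationError
from .rng import substream

__all__ = [
    "BackboneSpec",
    "register_backbone",
    "registry_names",
    "build_backbone",
    "count_params",
    "count_flops",
    "default_input_hw",
]

logger = logging.getLogger(__name__)

_REGISTRY: dict[str, Callable[[int, int, np.random.Generator], nn.Sequential]] = {}

#: Default square input resolution per backbone family.
_INPUT_HW = {"tiny": 64, "tiny_wide": 64, "tiny_deep": 64}


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture name plus its input/output interface.

    ``in_channels`` is 3 for an RGB frame and 2*F for a stack of F dense
    flow fields (x and y displacement planes per field).
    """

    name: str
    in_channels: int
    num_classes: int

    def __post_init__(self):
        if self.name not in _REGISTRY:
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; registered: {registry_names()}"
            )
        if self.in_channels < 1:
            raise ConfigurationError("in_channels must be positive")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")

    @property
    def display_name(self) -> str:
        """CamelCase name used in experiment-table row labels."""
        return "".join(part.capitalize() for part in self.name.split("_"))


def register_backbone(
    name: str, builder: Callable[[int, int, np.random.Generator], nn.Sequential]
) -> None:
    _REGISTRY[name] = builder


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def _conv_stack(
    widths: list[int], cin: int, num_classes: int, rng: np.random.Generator
) -> nn.Sequential:
    layers: list[nn.Layer] = []
    prev = cin
    for w in widths:
        layers += [nn.Conv2d(prev, w, 3, rng=rng), nn.ReLU(), nn.MaxPool2()]
        prev = w
    layers += [nn.GlobalAvgPool(), nn.Dense(prev, num_classes, rng=rng)]
    return nn.Sequential(layers, in_channels=cin, num_classes=num_classes)


register_backbone("tiny", lambda c, k, rng: _conv_stack([8, 16, 32], c, k, rng))
register_backbone("tiny_wide", lambda c, k, rng: _conv_stack([16, 32, 64], c, k, rng))
register_backbone(
    "tiny_deep", lambda c, k, rng: _conv_stack([8, 16, 32, 64], c, k, rng)
)


def default_input_hw(name: str) -> int:
    return _INPUT_HW.get(name, 64)


def build_backbone(spec: BackboneSpec, seed: int) -> nn.Sequential:
    """Instantiate a classifier network with seed-deterministic init.

    The same (spec, seed) always yields bitwise-identical initial
    parameters; different seeds yield different ones.
    """
    rng = substream(seed, "init", spec.name, spec.in_channels, spec.num_classes)
    return _REGISTRY[spec.name](spec.in_channels, spec.num_classes, rng)


def count_params(net: nn.Sequential) -> int:
    """Total scalar parameter count."""
    return int(sum(p.value.size for p in net.params()))


def count_flops(net: nn.Sequential, input_shape: tuple[int, int, int]) -> int:
    """Multiply-accumulate count of one forward pass on ``input_shape``.

    ``input_shape`` is (H, W, C) for a single sample.  Layers without a
    MAC model contribute zero; an unrecognized layer object is excluded
    with a warning.
    """
    shape = tuple(input_shape)
    total = 0
    for layer in net.layers:
        if not isinstance(layer, nn.Layer):
            logger.warning("count_flops: skipping unsupported layer %r", layer)
            continue
        macs, shape = layer.macs(shape)
        total += macs
    return int(total)
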