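"""Synthetic labeled behavior clips with controlled appearance/motion cues.

The generator emulates the structure of a single-animal behavior-clip
dataset: K classes, equal clip counts, a few seconds per clip at a fixed
frame rate, with class identity encoded jointly in the *texture* of a
moving foreground object (appearance cue, visible to an RGB classifier)
and in its *velocity field* (motion cue, visible to a flow classifier).

Class signatures are deliberately confounded pairwise: at least two
classes share a texture family (they can only be told apart by motion)
and at least two share a motion law (only appearance separates them).
An appearance-only and a motion-only classifier are therefore each
imperfect by construction, and late fusion of the two streams has
measurable headroom — the phenomenon the two-stream experiments probe.

Texture families: 0 stripes, 1 checkerboard, 2 dot lattice, 3 smooth
blobs.  Motion laws: 0 static, 1 linear drift, 2 oscillation,
3 random-walk jitter, 4 in-place rotation.  Per-clip nuisance variation
(object position, texture phase and orientation, color tint, pixel
noise) is drawn from named substreams of the root seed, so every emitted
pixel is a pure function of the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .data import ClipRecord, DatasetManifest, IOConfig, arrays_from_clips
from .errors import ConfigurationError
from .rng import spawn_seed, substream

__all__ = [
    "ClassSignature",
    "GeneratorConfig",
    "default_signatures",
    "generate_clip",
    "generate_clips_memory",
    "generate_dataset",
    "make_benchmark_data",
    "BEHAVIOR_NAMES",
]

logger = logging.getLogger(__name__)

TEXTURES = ("stripes", "checker", "dots", "blobs")
MOTIONS = ("static", "linear", "oscillation", "jitter", "rotation")

#: Default class names, matching a six-behavior pig ethogram.
BEHAVIOR_NAMES = ("drinking", "eating", "fighting", "investigating", "lying",
                  "walking")


@dataclass(frozen=True)
class ClassSignature:
    """Appearance/motion recipe of one class."""

    name: str
    texture_id: int
    motion_id: int
    appearance_noise: float = 0.5
    motion_noise: float = 0.2

    def __post_init__(self):
        if not (0 <= self.texture_id < len(TEXTURES)):
            raise ConfigurationError(f"texture_id out of range: {self.texture_id}")
        if not (0 <= self.motion_id < len(MOTIONS)):
            raise ConfigurationError(f"motion_id out of range: {self.motion_id}")
        for v in (self.appearance_noise, self.motion_noise):
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError("noise levels must lie in [0, 1]")


# six-behavior (texture_id, motion_id) mapping: walking/investigating share
# stripes, eating/fighting share checker, investigating/eating share
# oscillation — appearance alone and motion alone are both ambiguous
_SIX_CLASS_PAIRS = {
    "drinking": (3, 4),       # blobs,   rotation
    "eating": (1, 2),         # checker, oscillation
    "fighting": (1, 3),       # checker, jitter
    "investigating": (0, 2),  # stripes, oscillation
    "lying": (2, 0),          # dots,    static
    "walking": (0, 1),        # stripes, linear drift
}

# for other class counts: every prefix of length >= 3 keeps both a shared
# texture and a shared motion
_GENERIC_PAIRS = [
    (0, 1), (0, 2), (1, 2), (1, 3), (2, 0), (3, 4), (2, 1), (3, 2),
]


def default_signatures(num_classes: int = 6, appearance_noise: float = 0.5,
                       motion_noise: float = 0.2) -> list[ClassSignature]:
    if num_classes < 3 or num_classes > len(_GENERIC_PAIRS):
        raise ConfigurationError(
            f"default signatures support 3..{len(_GENERIC_PAIRS)} classes"
        )
    if num_classes == 6:
        items = list(_SIX_CLASS_PAIRS.items())
    else:
        items = [
            (f"class{i:02d}", _GENERIC_PAIRS[i]) for i in range(num_classes)
        ]
    return [
        ClassSignature(name, *pair, appearance_noise=appearance_noise,
                       motion_noise=motion_noise)
        for name, pair in items
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Benchmark-defining knobs; the defaults are the study conditions."""

    num_classes: int = 6
    clips_per_class: int = 60
    frames_per_clip: int = 32
    fps: float = 8.0
    height: int = 64
    width: int = 64
    seed: int = 0
    signatures: tuple[ClassSignature, ...] = ()

    def __post_init__(self):
        sigs = self.signatures or tuple(default_signatures(self.num_classes))
        if len(sigs) != self.num_classes:
            raise ConfigurationError("one signature per class required")
        pairs = [(s.texture_id, s.motion_id) for s in sigs]
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("class (texture, motion) pairs must be distinct")
        tex = [s.texture_id for s in sigs]
        mot = [s.motion_id for s in sigs]
        if len(set(tex)) == len(tex) or len(set(mot)) == len(mot):
            raise ConfigurationError(
                "at least two classes must share a texture family and at "
                "least two a motion law (stream complementarity)"
            )
        object.__setattr__(self, "signatures", tuple(sigs))

    @property
    def class_names(self) -> list[str]:
        return [s.name for s in self.signatures]


# ---------------------------------------------------------------------------
# rendering

def _texture(tex_id: int, u: np.ndarray, v: np.ndarray, rng_params: dict
             ) -> np.ndarray:
    lam = rng_params["wavelength"]
    if tex_id == 0:  # stripes
        return 0.5 + 0.5 * np.sin(2 * np.pi * u / lam + rng_params["phase"])
    if tex_id == 1:  # checker
        s = np.sin(2 * np.pi * u / lam + rng_params["phase"]) * np.sin(
            2 * np.pi * v / lam + rng_params["phase2"]
        )
        return np.where(s > 0, 0.95, 0.15)
    if tex_id == 2:  # dot lattice
        s = np.cos(2 * np.pi * u / lam + rng_params["phase"]) * np.cos(
            2 * np.pi * v / lam + rng_params["phase2"]
        )
        return np.where(s > 0.45, 0.95, 0.3)
    # smooth blobs: two incommensurate sinusoids
    s = np.sin(2 * np.pi * u / (1.7 * lam) + rng_params["phase"]) + np.sin(
        2 * np.pi * (u + v) / (2.3 * lam) + rng_params["phase2"]
    )
    return 0.5 + 0.25 * s


def _positions(motion_id: int, T: int, H: int, W: int, radius: float,
               motion_noise: float, rng: np.random.Generator) -> np.ndarray:
    """(T, 2) object-center trajectory (x, y), kept inside the frame."""
    center = np.array([W / 2, H / 2])
    margin = radius + 2.0
    lo, hi = margin, np.array([W, H]) - margin
    start = center + rng.uniform(-6, 6, size=2)  # seeded placement
    t = np.arange(T)[:, None]
    if motion_id == 0:  # static
        pos = np.repeat(start[None, :], T, axis=0).astype(np.float64)
    elif motion_id == 1:  # linear drift, reflecting at the frame margins
        speed = rng.uniform(1.2, 1.8)
        ang = rng.uniform(0, 2 * np.pi)
        v = speed * np.array([np.cos(ang), np.sin(ang)])
        pos = _reflect(start + v * t, lo, hi - 1)
    elif motion_id == 2:  # oscillation
        amp = rng.uniform(6.0, 8.0)
        # half-period of 4-5 frames: a velocity sign flip is always
        # visible inside a 5-field flow window
        period = rng.uniform(8.0, 10.0)
        ang = rng.uniform(0, 2 * np.pi)
        d = np.array([np.cos(ang), np.sin(ang)])
        phase = rng.uniform(0, 2 * np.pi)
        pos = start + amp * np.sin(2 * np.pi * t / period + phase) * d
    elif motion_id == 3:  # random-walk jitter
        sigma = rng.uniform(1.4, 2.0)
        steps = rng.normal(0, sigma, size=(T, 2))
        pos = start + np.cumsum(steps, axis=0)
    else:  # rotation: centroid fixed (spin handled via texture angle)
        pos = np.repeat(start[None, :], T, axis=0).astype(np.float64)
    if motion_noise > 0:
        pos = pos + rng.normal(0, motion_noise, size=(T, 2))
    return np.clip(pos, lo, hi - 1)


def _reflect(pos: np.ndarray, lo, hi) -> np.ndarray:
    """Fold an unbounded trajectory back into [lo, hi] (billiard reflection)."""
    span = np.asarray(hi) - np.asarray(lo)
    phase = np.mod(pos - lo, 2 * span)
    return lo + np.where(phase > span, 2 * span - phase, phase)


def generate_clip(signature: ClassSignature, frames: int, seed: int,
                  height: int = 64, width: int = 64) -> np.ndarray:
    """Render one clip as a (T, H, W, 3) float32 stack in [0, 1]."""
    rng = substream(seed, "clip")
    H, W, T = height, width, frames
    radius = rng.uniform(12.0, 15.0)
    tex_params = {
        "wavelength": rng.uniform(5.0, 7.0),
        "phase": rng.uniform(0, 2 * np.pi),
        "phase2": rng.uniform(0, 2 * np.pi),
    }
    theta0 = rng.uniform(0, 2 * np.pi)
    spin = rng.uniform(0.18, 0.26) * rng.choice([-1.0, 1.0]) \
        if signature.motion_id == 4 else 0.0
    tint = rng.uniform(0.7, 1.0, size=3)
    bg_level = rng.uniform(0.35, 0.5)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    # low-frequency static background pattern
    bphase = rng.uniform(0, 2 * np.pi, size=2)
    bg = bg_level + 0.05 * np.sin(2 * np.pi * xx / 37 + bphase[0]) * np.sin(
        2 * np.pi * yy / 41 + bphase[1]
    )
    pos = _positions(signature.motion_id, T, H, W, radius,
                     signature.motion_noise, rng)
    # appearance noise: mostly a static per-clip field (fixed-pattern, like
    # sensor grain — invisible to flow matching) plus a small temporal part
    noise_sd = 0.15 * signature.appearance_noise
    if noise_sd > 0:
        static_noise = rng.normal(0, noise_sd, size=(H, W))
        noise = static_noise + rng.normal(0, 0.3 * noise_sd, size=(T, H, W))
    else:
        noise = None

    out = np.empty((T, H, W, 3), dtype=np.float32)
    for t in range(T):
        cx, cy = pos[t]
        theta = theta0 + spin * t
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        tex = _texture(signature.texture_id, u, v, tex_params)
        dist = np.sqrt(dx * dx + dy * dy)
        mask = 1.0 / (1.0 + np.exp((dist - radius) / 1.0))  # soft edge
        gray = bg * (1 - mask)
        frame = gray[..., None] + (mask * tex)[..., None] * tint
        if noise is not None:
            frame = frame + noise[t][..., None]
        out[t] = np.clip(frame, 0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# dataset emission

def generate_clips_memory(config: GeneratorConfig
                          ) -> tuple[list[tuple[int, np.ndarray]], list[str]]:
    """All clips as in-memory (label_index, frames) pairs, plus class names."""
    clips = []
    for ci, sig in enumerate(config.signatures):
        for k in range(config.clips_per_class):
            seed = spawn_seed(config.seed, "clip", sig.name, k)
            clips.append(
                (ci, generate_clip(sig, config.frames_per_clip, seed,
                                   config.height, config.width))
            )
    return clips, config.class_names


def generate_dataset(config: GeneratorConfig, out_dir: str | Path,
                     overwrite: bool = False) -> DatasetManifest:
    """Write the dataset as frame directories and return its manifest.

    Layout: ``out/<class>/<class>_<idx>/frame_<t>.png`` with a
    ``_meta.json`` (fps) per clip and ``manifest.csv`` at the root.
    Bitwise reproducible for a given configuration.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass overwrite=True"
        )
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for sig in config.signatures:
        for k in range(config.clips_per_class):
            seed = spawn_seed(config.seed, "clip", sig.name, k)
            frames = generate_clip(sig, config.frames_per_clip, seed,
                                   config.height, config.width)
            clip_dir = out / sig.name / f"{sig.name}_{k:03d}"
            clip_dir.mkdir(parents=True, exist_ok=True)
            for t in range(frames.shape[0]):
                img = np.round(frames[t] * 255.0).astype(np.uint8)
                iio.imwrite(clip_dir / f"frame_{t:04d}.png", img)
            (clip_dir / "_meta.json").write_text(json.dumps({"fps": config.fps}))
            records.append(
                ClipRecord(path=str(clip_dir), label=sig.name,
                           num_frames=config.frames_per_clip, fps=config.fps)
            )
    manifest = DatasetManifest(records=records, classes=config.class_names)
    manifest.to_csv(out / "manifest.csv")
    return manifest


def make_benchmark_data(config: GeneratorConfig, io_config: IOConfig,
                        train_fraction: float = 0.8, split_seed: int | None = None
                        ):
    """Generate, split per class and assemble network-ready arrays.

    Returns ``(train, test)`` where each is ``(x_rgb, x_flow, y)``.  The
    split uses the same seeded per-class shuffle and round-half-up rule
    as :func:`tsml.data.split_per_class`; no disk I/O is involved.
    """
    split_seed = config.seed if split_seed is None else split_seed
    clips, classes = generate_clips_memory(config)
    train_clips, test_clips = [], []
    for ci, cls in enumerate(classes):
        idx = [i for i, (label, _) in enumerate(clips) if label == ci]
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        order = substream(split_seed, "split", cls).permutation(len(idx))
        for rank, j in enumerate(order):
            (train_clips if rank < n_train else test_clips).append(clips[idx[j]])
    K = len(classes)
    return (
        arrays_from_clips(train_clips, io_config, K),
        arrays_from_clips(test_clips, io_config, K),
    )
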