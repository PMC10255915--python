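"""Clip decoding, frame sampling, optical flow, manifests and splits.

A dataset on disk is one directory per class, each containing clips as
either frame directories (numbered PNG/JPEG files, optionally with a
``_meta.json`` recording fps) or video container files.  The manifest
indexes every clip with ``path,label,split,num_frames,fps`` columns;
class order is the order of first appearance in the manifest and is the
label-index mapping used everywhere downstream.

Network inputs are assembled per clip as

* an RGB stack: the center frame(s) of the clip, resized, in [0, 1];
* a flow stack: F dense optical-flow fields from the F+1 consecutive
  frames centered on the same point, displacements clipped to
  ``flow_clip`` px and rescaled to [-1, 1].

Flow is the expensive step, so it can be cached per clip (compressed
``.npz`` plus a JSON sidecar keying method, depth and frame count; a
stale sidecar causes a recompute, never a wrong read).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.registration import optical_flow_ilk, optical_flow_tvl1
from skimage.transform import resize

from .errors import ConfigurationError, InvalidInputError
from .rng import substream

__all__ = [
    "ClipRecord",
    "DatasetManifest",
    "IOConfig",
    "VideoSample",
    "scan_dataset",
    "split_per_class",
    "sample_indices",
    "sample_frames",
    "compute_flow",
    "read_clip_frames",
    "load_sample",
    "load_split_arrays",
    "arrays_from_clips",
]

logger = logging.getLogger(__name__)

_IMAGE_EXTS = {".png", ".jpg", ".jpeg"}
_VIDEO_EXTS = {".mp4", ".avi"}
FLOW_METHODS = ("ilk", "tvl1")


# ---------------------------------------------------------------------------
# manifest

@dataclass(frozen=True)
class ClipRecord:
    path: str
    label: str
    split: str = "train"
    num_frames: int = 0
    fps: float = 25.0


@dataclass
class DatasetManifest:
    """Ordered clip records plus the fixed class list."""

    records: list[ClipRecord]
    classes: list[str]

    def __post_init__(self):
        unknown = {r.label for r in self.records} - set(self.classes)
        if unknown:
            raise InvalidInputError(f"records with labels outside class list: {unknown}")

    @property
    def counts(self) -> dict[str, int]:
        c = {cls: 0 for cls in self.classes}
        for r in self.records:
            c[r.label] += 1
        return c

    @property
    def total(self) -> int:
        return len(self.records)

    def label_index(self, label: str) -> int:
        return self.classes.index(label)

    def subset(self, split: str) -> list[ClipRecord]:
        return [r for r in self.records if r.split == split]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001
            raise InvalidInputError(f"malformed manifest {path}: {exc}") from exc
        needed = {"path", "label", "split", "num_frames", "fps"}
        missing = needed - set(df.columns)
        if missing:
            raise InvalidInputError(
                f"manifest {path} is missing columns {sorted(missing)}"
            )
        records = [
            ClipRecord(
                path=str(row.path),
                label=str(row.label),
                split=str(row.split),
                num_frames=int(row.num_frames),
                fps=float(row.fps),
            )
            for row in df.itertuples()
        ]
        classes = list(dict.fromkeys(r.label for r in records))
        return cls(records=records, classes=classes)


def _clip_entries(class_dir: Path) -> list[Path]:
    entries = []
    for p in sorted(class_dir.iterdir()):
        if p.is_dir():
            entries.append(p)
        elif p.suffix.lower() in _VIDEO_EXTS:
            entries.append(p)
        elif p.suffix.lower() in _IMAGE_EXTS or p.name.startswith("."):
            continue
        else:
            logger.warning("skipping %s: unknown extension", p)
    return entries


def _frame_files(clip_dir: Path) -> list[Path]:
    return sorted(p for p in clip_dir.iterdir() if p.suffix.lower() in _IMAGE_EXTS)


def _clip_meta(clip: Path) -> tuple[int, float]:
    """(num_frames, fps) for a clip path without decoding pixel data."""
    if clip.is_dir():
        n = len(_frame_files(clip))
        fps = 25.0
        meta = clip / "_meta.json"
        if meta.exists():
            fps = float(json.loads(meta.read_text()).get("fps", fps))
        return n, fps
    try:
        props = iio.improps(clip, plugin="pyav")
        return int(props.shape[0]), 25.0
    except Exception as exc:  # noqa: BLE001
        raise InvalidInputError(
            f"cannot read video container {clip}: {exc}; "
            "use frame directories if no video plugin is available"
        ) from exc


def scan_dataset(root_dir: str | Path, class_list: list[str] | None = None
                 ) -> DatasetManifest:
    """Index ``root/<class>/<clip>`` into a manifest (lexicographic order)."""
    root = Path(root_dir)
    if not root.is_dir():
        raise InvalidInputError(f"dataset root {root} is not a directory")
    classes = class_list or sorted(p.name for p in root.iterdir() if p.is_dir())
    if not classes:
        raise InvalidInputError(f"dataset root {root} contains no class directories")
    records = []
    for cls in classes:
        class_dir = root / cls
        if not class_dir.is_dir():
            raise InvalidInputError(f"missing class directory {class_dir}")
        clips = _clip_entries(class_dir)
        if not clips:
            raise InvalidInputError(f"class {cls!r} has no clips under {class_dir}")
        for clip in clips:
            n, fps = _clip_meta(clip)
            records.append(
                ClipRecord(path=str(clip), label=cls, num_frames=n, fps=fps)
            )
    return DatasetManifest(records=records, classes=list(classes))


def split_per_class(manifest: DatasetManifest, train_fraction: float, seed: int
                    ) -> DatasetManifest:
    """Seeded per-class shuffle and split into train/test.

    The per-class train count is round-half-up(train_fraction * n): with
    the 80/20 convention this reproduces standard published train/test
    totals exactly.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError("train_fraction must lie strictly in (0, 1)")
    new_records = list(manifest.records)
    for cls in manifest.classes:
        idx = [i for i, r in enumerate(manifest.records) if r.label == cls]
        if len(idx) < 2:
            raise InvalidInputError(
                f"class {cls!r} has {len(idx)} clip(s); need at least 2 to split"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        order = substream(seed, "split", cls).permutation(len(idx))
        for rank, j in enumerate(order):
            new_records[idx[j]] = replace(
                manifest.records[idx[j]],
                split="train" if rank < n_train else "test",
            )
    return DatasetManifest(records=new_records, classes=list(manifest.classes))


# ---------------------------------------------------------------------------
# frames and flow

def sample_indices(num_available: int, num_frames: int, mode: str = "uniform",
                   seed: int = 0) -> np.ndarray:
    """Frame indices for temporal sampling.

    ``uniform`` picks evenly spaced indices (deterministic, endpoints
    included); ``random`` picks a seeded sorted sample without
    replacement.
    """
    if num_frames > num_available:
        raise InvalidInputError(
            f"requested {num_frames} frames from a {num_available}-frame clip"
        )
    if mode == "uniform":
        return np.linspace(0, num_available - 1, num_frames).astype(np.int64)
    if mode == "random":
        rng = substream(seed, "frame_sample", num_available, num_frames)
        return np.sort(rng.choice(num_available, size=num_frames, replace=False))
    raise ConfigurationError(f"unknown sampling mode {mode!r}")


def sample_frames(frames: np.ndarray, num_frames: int, mode: str = "uniform",
                  seed: int = 0) -> np.ndarray:
    """Apply :func:`sample_indices` to a (T, H, W[, C]) frame stack."""
    return frames[sample_indices(frames.shape[0], num_frames, mode, seed)]


def _to_gray(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:
        return frames @ np.array([0.299, 0.587, 0.114], dtype=frames.dtype)
    return frames


def compute_flow(frames: np.ndarray, method: str = "ilk") -> np.ndarray:
    """Dense forward optical flow between consecutive frames.

    ``frames`` is (T, H, W) grayscale or (T, H, W, 3) RGB with T >= 2
    and constant spatial size.  Returns (T-1, H, W, 2) displacement
    fields in pixels/frame, last axis ordered (dx, dy).
    """
    f = np.asarray(frames, dtype=np.float32)
    if f.ndim not in (3, 4) or f.shape[0] < 2:
        raise InvalidInputError(
            f"need >= 2 frames of constant size, got shape {f.shape}"
        )
    if method not in FLOW_METHODS:
        raise ConfigurationError(f"flow method must be one of {FLOW_METHODS}")
    g = _to_gray(f)
    solver = optical_flow_ilk if method == "ilk" else optical_flow_tvl1
    out = np.empty((g.shape[0] - 1, g.shape[1], g.shape[2], 2), dtype=np.float32)
    for t in range(g.shape[0] - 1):
        # returned as (row, col) displacement of frame t content in frame t+1
        vr, vc = solver(g[t], g[t + 1])
        out[t, ..., 0] = vc  # dx
        out[t, ..., 1] = vr  # dy
    return out


def read_clip_frames(path: str | Path) -> np.ndarray:
    """Decode a clip into a (T, H, W, 3) float32 stack in [0, 1]."""
    p = Path(path)
    if p.is_dir():
        files = _frame_files(p)
        if not files:
            raise InvalidInputError(f"frame directory {p} contains no images")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        try:
            frames = iio.imread(p, plugin="pyav")
        except Exception as exc:  # noqa: BLE001
            raise InvalidInputError(f"cannot decode video {p}: {exc}") from exc
    if frames.ndim == 3:
        frames = np.repeat(frames[..., None], 3, axis=-1)
    frames = frames.astype(np.float32)
    if frames.max() > 1.5:
        frames /= 255.0
    return frames


# ---------------------------------------------------------------------------
# sample assembly

@dataclass(frozen=True)
class IOConfig:
    """How clips become network inputs."""

    height: int = 64
    width: int = 64
    flow_depth: int = 5  # F: flow fields per stack
    flow_method: str = "ilk"
    flow_clip: float = 20.0  # px; displacements clipped then scaled to [-1, 1]
    rgb_frames: int = 1  # frames in the appearance stack
    cache_dir: str | None = None
    # network-input standardization (nominal constants, applied when the
    # batched arrays are assembled; the per-sample stacks keep their
    # documented units)
    normalize: bool = True
    rgb_mean: float = 0.45
    rgb_std: float = 0.25
    flow_scale: float = 1.0  # px of displacement mapped to input value 1.0

    def __post_init__(self):
        if self.flow_method not in FLOW_METHODS:
            raise ConfigurationError(f"flow method must be one of {FLOW_METHODS}")
        if self.flow_depth < 1 or self.rgb_frames < 1:
            raise ConfigurationError("flow_depth and rgb_frames must be >= 1")

    @property
    def rgb_channels(self) -> int:
        return 3 * self.rgb_frames

    @property
    def flow_channels(self) -> int:
        return 2 * self.flow_depth


@dataclass(frozen=True)
class VideoSample:
    """One clip as network-ready stacks plus its label index."""

    rgb_stack: np.ndarray  # (F_rgb, H, W, 3) in [0, 1]
    flow_stack: np.ndarray  # (F, H, W, 2) in [-1, 1]
    label_index: int
    num_classes: int

    def rgb_input(self) -> np.ndarray:
        """(H, W, 3*F_rgb) channel-stacked appearance input."""
        f, h, w, c = self.rgb_stack.shape
        return np.ascontiguousarray(
            self.rgb_stack.transpose(1, 2, 0, 3).reshape(h, w, f * c)
        )

    def flow_input(self) -> np.ndarray:
        """(H, W, 2*F) channel-stacked motion input."""
        f, h, w, c = self.flow_stack.shape
        return np.ascontiguousarray(
            self.flow_stack.transpose(1, 2, 0, 3).reshape(h, w, f * c)
        )


def _resize_stack(frames: np.ndarray, h: int, w: int) -> np.ndarray:
    if frames.shape[1] == h and frames.shape[2] == w:
        return frames
    return np.stack(
        [resize(fr, (h, w), preserve_range=True, anti_aliasing=True) for fr in frames]
    ).astype(np.float32)


def _cache_key(record: ClipRecord, config: IOConfig) -> str:
    raw = f"{record.path}|{config.flow_method}|{config.flow_depth}"
    return hashlib.md5(raw.encode()).hexdigest()


def _flow_window(num_frames: int, depth: int) -> tuple[int, int]:
    """Start index and length of the centered F+1-frame flow window."""
    need = depth + 1
    start = max(0, num_frames // 2 - need // 2)
    return start, need


def _raw_flow(frames: np.ndarray, record: ClipRecord, config: IOConfig) -> np.ndarray:
    start, need = _flow_window(frames.shape[0], config.flow_depth)
    window = frames[start : start + need]
    if config.cache_dir is None:
        return compute_flow(window, config.flow_method)
    cache = Path(config.cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    key = _cache_key(record, config)
    npz, sidecar = cache / f"{key}.npz", cache / f"{key}.json"
    meta = {
        "path": record.path,
        "method": config.flow_method,
        "depth": config.flow_depth,
        "num_frames": int(frames.shape[0]),
    }
    if npz.exists() and sidecar.exists():
        try:
            if json.loads(sidecar.read_text()) == meta:
                with np.load(npz) as data:
                    return data["flow"]
            logger.warning("flow cache mismatch for %s; recomputing", record.path)
        except Exception:  # noqa: BLE001
            logger.warning("unreadable flow cache for %s; recomputing", record.path)
    flow = compute_flow(window, config.flow_method)
    np.savez_compressed(npz, flow=flow)
    sidecar.write_text(json.dumps(meta))
    return flow


def _assemble(frames: np.ndarray, record: ClipRecord, config: IOConfig,
              label_index: int, num_classes: int) -> VideoSample:
    frames = _resize_stack(frames, config.height, config.width)
    if frames.shape[0] < config.flow_depth + 1:
        raise InvalidInputError(
            f"clip {record.path} has {frames.shape[0]} frames; "
            f"need {config.flow_depth + 1} for the flow stack"
        )
    flow = _raw_flow(frames, record, config)
    flow = np.clip(flow, -config.flow_clip, config.flow_clip) / config.flow_clip
    # appearance frames: centered within the clip (uniform if more than one)
    rgb_idx = sample_indices(frames.shape[0], config.rgb_frames + 2, "uniform")[1:-1] \
        if config.rgb_frames > 1 else np.array([frames.shape[0] // 2])
    rgb = frames[rgb_idx]
    return VideoSample(
        rgb_stack=rgb.astype(np.float32),
        flow_stack=flow.astype(np.float32),
        label_index=label_index,
        num_classes=num_classes,
    )


def load_sample(record: ClipRecord, config: IOConfig, manifest: DatasetManifest
                ) -> VideoSample:
    """Decode one clip from disk into a :class:`VideoSample`."""
    frames = read_clip_frames(record.path)
    return _assemble(
        frames, record, config, manifest.label_index(record.label),
        len(manifest.classes),
    )


def load_split_arrays(manifest: DatasetManifest, split: str, config: IOConfig,
                      progress: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load one split as batched arrays (x_rgb, x_flow, y)."""
    records = manifest.subset(split)
    if not records:
        raise InvalidInputError(f"manifest has no records with split={split!r}")
    iterator = records
    if progress:
        from tqdm import tqdm

        iterator = tqdm(records, desc=f"loading {split}")
    samples = [load_sample(r, config, manifest) for r in iterator]
    return _stack_samples(samples, config)


def arrays_from_clips(clips: list[tuple[int, np.ndarray]], config: IOConfig,
                      num_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-memory counterpart of :func:`load_split_arrays`.

    ``clips`` is a list of (label_index, frames) pairs, as produced by
    the synthetic generator; avoids any disk round-trip.
    """
    samples = [
        _assemble(
            frames,
            ClipRecord(path=f"<memory:{i}>", label=str(label)),
            config, label, num_classes,
        )
        for i, (label, frames) in enumerate(clips)
    ]
    return _stack_samples(samples, config)


def _stack_samples(samples: list[VideoSample], config: IOConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x_rgb = np.stack([s.rgb_input() for s in samples])
    x_flow = np.stack([s.flow_input() for s in samples])
    if config.normalize:
        x_rgb = (x_rgb - config.rgb_mean) / config.rgb_std
        x_flow = x_flow * (config.flow_clip / config.flow_scale)
    y = np.array([s.label_index for s in samples], dtype=np.int64)
    return x_rgb.astype(np.float32), x_flow.astype(np.float32), y
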