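"""Generate a small synthetic behavior-clip dataset and inspect it.

Writes frame-directory clips for six classes whose identity is encoded
jointly in texture (appearance) and velocity field (motion), then
contrasts a static class with a drifting one through their measured
optical flow — the signal that makes the motion stream informative.
"""

import tempfile
from pathlib import Path

import numpy as np

from tsml import GeneratorConfig, compute_flow, generate_dataset
from tsml.data import read_clip_frames

out = Path(tempfile.mkdtemp()) / "clips"
config = GeneratorConfig(clips_per_class=3, frames_per_clip=12, seed=11)
manifest = generate_dataset(config, out)

print(f"dataset at {out}")
for cls, n in manifest.counts.items():
    print(f"  {cls:15s} {n} clips")
print(f"total {manifest.total} clips, classes: {manifest.classes}")

# lying is static, walking drifts: same pipeline, very different motion
for cls in ("lying", "walking"):
    record = next(r for r in manifest.records if r.label == cls)
    frames = read_clip_frames(record.path)
    flow = compute_flow(frames[:6])
    print(f"{cls:15s} mean |flow| = {np.abs(flow).mean():.3f} px/frame")

print()
print("The flow magnitudes show motion alone separates these classes even")
print("though their appearance pipelines are identical in structure.")
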