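"""File formats: 16-bit PNG depth stacks, keypoint JSON, manifests.

Depth stacks are written either as a directory of 16-bit PNG frames
(``frame_0000.png`` ...) or as one compressed ``.npz`` archive.
Keypoint tracks are JSON with per-frame ``name -> [x, y]`` maps plus
the camera geometry, and dataset manifests are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .sequences import KEYPOINT_NAMES, WalkingSequence

__all__ = [
    "write_depth_stack",
    "read_depth_stack",
    "write_keypoints",
    "read_keypoints",
    "write_sequence",
    "read_sequence",
    "write_manifest",
]


def write_depth_stack(stack: np.ndarray, out: Path, fmt: str = "png") -> Path:
    """Write a (T, H, W) mm depth stack as 16-bit PNGs or an npz archive."""
    out = Path(out)
    stack = np.asarray(stack)
    if fmt == "npz":
        out = out.with_suffix(".npz")
        np.savez_compressed(out, depth=stack.astype(np.float32))
        return out
    if fmt != "png":
        raise ValueError(f"unknown depth format {fmt!r}")
    out.mkdir(parents=True, exist_ok=True)
    for t, frame in enumerate(stack):
        iio.imwrite(
            out / f"frame_{t:04d}.png",
            np.round(frame).clip(0, 65535).astype(np.uint16),
        )
    return out


def read_depth_stack(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        return np.load(path)["depth"].astype(float)
    frames = sorted(path.glob("frame_*.png"))
    if not frames:
        raise FileNotFoundError(f"no depth frames under {path}")
    return np.stack([iio.imread(f).astype(float) for f in frames])


def write_keypoints(seq: WalkingSequence, out: Path) -> Path:
    out = Path(out)
    doc = {
        "fps": seq.fps,
        "scale_cm_per_px": seq.scale_cm_per_px,
        "camera_height_mm": seq.camera_height_mm,
        "keypoints": [
            {
                name: [float(v) for v in seq.keypoints[name][t]]
                for name in KEYPOINT_NAMES
            }
            for t in range(seq.n_frames)
        ],
    }
    out.write_text(json.dumps(doc, indent=1))
    return out


def read_keypoints(path: Path) -> dict:
    doc = json.loads(Path(path).read_text())
    T = len(doc["keypoints"])
    tracks = {
        name: np.array(
            [doc["keypoints"][t][name] for t in range(T)], dtype=float
        )
        for name in KEYPOINT_NAMES
    }
    return {
        "keypoints": tracks,
        "fps": doc["fps"],
        "scale_cm_per_px": doc["scale_cm_per_px"],
        "camera_height_mm": doc["camera_height_mm"],
    }


def write_sequence(
    seq: WalkingSequence, out_dir: Path, depth_fmt: str = "npz"
) -> None:
    """Write one sequence (depth, keypoints, optional frames) to a folder."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_depth_stack(seq.depth_stack, out_dir / "depth", fmt=depth_fmt)
    write_keypoints(seq, out_dir / "keypoints.json")
    if seq.frames is not None:
        np.savez_compressed(out_dir / "frames.npz", frames=seq.frames)


def read_sequence(seq_dir: Path, label: str | None = None) -> WalkingSequence:
    seq_dir = Path(seq_dir)
    depth_path = seq_dir / "depth.npz"
    if not depth_path.exists():
        depth_path = seq_dir / "depth"
    stack = read_depth_stack(depth_path)
    meta = read_keypoints(seq_dir / "keypoints.json")
    frames = None
    frames_path = seq_dir / "frames.npz"
    if frames_path.exists():
        frames = np.load(frames_path)["frames"]
    return WalkingSequence(
        depth_stack=stack,
        keypoints=meta["keypoints"],
        frames=frames,
        scale_cm_per_px=meta["scale_cm_per_px"],
        camera_height_mm=meta["camera_height_mm"],
        fps=meta["fps"],
        label=label,
        sequence_id=seq_dir.name,
    )


def write_manifest(rows: list[dict], out: Path) -> Path:
    out = Path(out)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out
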