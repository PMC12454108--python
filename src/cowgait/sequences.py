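"""Core in-memory containers for overhead walking sequences.

A walking sequence is the unit of analysis: a time-ordered stack of
overhead depth frames (mm, ``0`` marks a void pixel), per-frame pixel
coordinates of the eight back keypoints, optional 8-bit textured frames
for optical flow, and the camera geometry needed to convert pixels and
depth values into centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical names of the eight back keypoints, in template order
#: (front of the animal first).
KEYPOINT_NAMES: tuple[str, ...] = (
    "poll",
    "withers",
    "left_scapula",
    "right_scapula",
    "lumbar",
    "left_tuber_coxae",
    "right_tuber_coxae",
    "sacral_tuber",
)

#: The three spine landmarks used for back curvature / vertical
#: oscillation, ordered front to rear.
SPINE_NAMES: tuple[str, ...] = ("withers", "lumbar", "sacral_tuber")

#: Severity grades, ordered by increasing lameness.
CLASS_LABELS: tuple[str, ...] = ("sound", "mild", "severe")


@dataclass
class WalkingSequence:
    """One cow walking past the overhead camera.

    Parameters
    ----------
    depth_stack : ndarray, shape (T, H, W)
        Depth in millimetres; 0 encodes a void (no return) pixel.
    keypoints : dict
        Maps each of the eight keypoint names to a ``(T, 2)`` float array
        of ``(x, y)`` pixel coordinates (x = column, y = row, 0-based).
    frames : ndarray, shape (T, H, W), optional
        8-bit textured frames used for optical-flow motion analysis.
    scale_cm_per_px : float
        Ground-plane scale at back height.
    camera_height_mm : float
        Mount height of the depth camera above the floor.
    fps : float
        Frame rate of the recording.
    label : str, optional
        Severity grade (``sound`` / ``mild`` / ``severe``) when known.
    """

    depth_stack: np.ndarray
    keypoints: dict[str, np.ndarray]
    scale_cm_per_px: float
    camera_height_mm: float
    fps: float = 30.0
    frames: np.ndarray | None = None
    label: str | None = None
    sequence_id: str = field(default="seq")

    def __post_init__(self) -> None:
        self.depth_stack = np.asarray(self.depth_stack, dtype=float)
        if self.depth_stack.ndim != 3:
            raise ValueError("depth_stack must be a (T, H, W) array")
        if self.n_frames < 3:
            raise ValueError("a walking sequence needs at least 3 frames")
        if self.scale_cm_per_px <= 0:
            raise ValueError("scale_cm_per_px must be positive")
        missing = [k for k in KEYPOINT_NAMES if k not in self.keypoints]
        if missing:
            raise ValueError(f"missing keypoint tracks: {missing}")
        T, H, W = self.depth_stack.shape
        for name in KEYPOINT_NAMES:
            track = np.asarray(self.keypoints[name], dtype=float)
            if track.shape != (T, 2):
                raise ValueError(
                    f"keypoint track {name!r} must have shape ({T}, 2)"
                )
            self.keypoints[name] = track
            x, y = track[:, 0], track[:, 1]
            if (x < 0).any() or (x > W - 1).any() or (y < 0).any() or (y > H - 1).any():
                raise ValueError(f"keypoint {name!r} leaves the image bounds")
        if self.frames is not None and self.frames.shape != (T, H, W):
            raise ValueError("frames must match depth_stack shape")

    @property
    def n_frames(self) -> int:
        return self.depth_stack.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.depth_stack.shape[1:]


@dataclass
class SimulatedSequence(WalkingSequence):
    """A :class:`WalkingSequence` produced by the gait simulator.

    Carries the per-sequence feature targets the renderer realised, so
    round-trip tests can compare extracted features against them.
    """

    targets: dict[str, float] = field(default_factory=dict)
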