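import numpy as np
import pytest

from cowgait.sequences import KEYPOINT_NAMES, WalkingSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sequence(
    depths_mm: dict[str, np.ndarray],
    tracks_px: dict[str, np.ndarray] | None = None,
    T: int = 5,
    shape: tuple[int, int] = (120, 80),
    scale: float = 1.0,
    camera_height_mm: float = 3200.0,
    floor_mm: float = 2500.0,
    frames: np.ndarray | None = None,
) -> WalkingSequence:
    """Hand-built sequence: keypoints on a simple layout, depth painted
    as constant 5x5 patches so the 3x3-median lookup is exact."""
    H, W = shape
    if tracks_px is None:
        base = {
            "poll": (40, 100),
            "withers": (40, 80),
            "left_scapula": (55, 72),
            "right_scapula": (25, 72),
            "lumbar": (40, 50),
            "left_tuber_coxae": (54, 28),
            "right_tuber_coxae": (26, 28),
            "sacral_tuber": (40, 20),
        }
        tracks_px = {
            name: np.tile(np.asarray(xy, dtype=float), (T, 1))
            for name, xy in base.items()
        }
    T = next(iter(tracks_px.values())).shape[0]
    depth = np.full((T, H, W), floor_mm)
    for t in range(T):
        for name in KEYPOINT_NAMES:
            d = depths_mm.get(name, 1800.0)
            d_t = float(d[t]) if np.ndim(d) else float(d)
            x = int(round(tracks_px[name][t, 0]))
            y = int(round(tracks_px[name][t, 1]))
            depth[t, y - 2 : y + 3, x - 2 : x + 3] = d_t
    return WalkingSequence(
        depth_stack=depth,
        keypoints={k: v.copy() for k, v in tracks_px.items()},
        scale_cm_per_px=scale,
        camera_height_mm=camera_height_mm,
        frames=frames,
    )


@pytest.fixture
def make_seq():
    return make_sequence
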