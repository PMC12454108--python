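"""Six overhead-view lameness features from a walking sequence.

Lame cows arch the back, nod the head, sway and load the two body sides
unevenly.  From an overhead depth + RGB recording these manifestations
are quantified as:

========  =====  ======================================================
feature   unit   definition
========  =====  ======================================================
BC        1/cm   back curvature — max over frames of the curvature of
                 the circle through withers / lumbar / sacral tuber in
                 the sagittal plane (along-spine distance vs height)
MAI       —      movement asymmetry index — |muL - muR| / (muL + muR)
                 of mean dense-flow magnitude over the left and right
                 body halves
VOB       cm     vertical oscillation of the back — max temporal depth
                 range among withers, lumbar, sacral tuber
VOH       cm     vertical oscillation of the head — temporal depth
                 range at the poll
TI        cm     trunk inclination — max |left - right| depth
                 difference of the scapula and tuber-coxae pairs
LSAS      cm     lateral sway amplitude of the spine — max horizontal
                 peak-to-valley excursion of scapula midpoint, lumbar
                 and sacral tuber
========  =====  ======================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.registration import optical_flow_ilk

from .preprocess import foreground_mask
from .sequences import SPINE_NAMES, WalkingSequence

__all__ = [
    "FEATURE_NAMES",
    "GaitFeatureVector",
    "circumcircle_curvature",
    "back_curvature",
    "split_left_right",
    "flow_fields",
    "movement_asymmetry_index",
    "vertical_oscillation_back",
    "vertical_oscillation_head",
    "trunk_inclination",
    "lateral_sway_amplitude",
    "extract_all",
    "extract_table",
]

#: Canonical feature order used in tables and CSV output.
FEATURE_NAMES: tuple[str, ...] = ("BC", "MAI", "VOB", "VOH", "TI", "LSAS")

_COLLINEAR_AREA = 1e-9


@dataclass
class GaitFeatureVector:
    """The six scalar gait features of one sequence.

    ``mai`` is ``None`` when the sequence has no textured frames to
    compute optical flow from.
    """

    bc: float
    mai: float | None
    vob: float
    voh: float
    ti: float
    lsas: float

    def as_dict(self) -> dict[str, float | None]:
        return {
            "BC": self.bc,
            "MAI": self.mai,
            "VOB": self.vob,
            "VOH": self.voh,
            "TI": self.ti,
            "LSAS": self.lsas,
        }


def circumcircle_curvature(p1, p2, p3) -> float:
    """Curvature 1/R of the circle through three planar points (cm).

    Uses k = 4 * Area / (|a| |b| |c|).  Collinear points (triangle area
    below 1e-9) give curvature 0; coincident points are a degenerate
    input and raise.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    if min(a, b, c) < 1e-12:
        raise ValueError("coincident points have no unique circumcircle")
    u, v = p2 - p1, p3 - p1
    area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
    if area < _COLLINEAR_AREA:
        return 0.0
    return float(4.0 * area / (a * b * c))


def _keypoint_depth(frame: np.ndarray, xy: np.ndarray) -> float:
    """Depth (mm) at a keypoint: median of the valid 3x3 neighbourhood.

    Tolerates single-pixel sensor noise at the looked-up location.
    Returns NaN when the whole neighbourhood is void.
    """
    H, W = frame.shape
    x = int(round(float(xy[0])))
    y = int(round(float(xy[1])))
    patch = frame[
        max(0, y - 1) : min(H, y + 2), max(0, x - 1) : min(W, x + 2)
    ]
    vals = patch[patch > 0]
    if vals.size == 0:
        return float("nan")
    return float(np.median(vals))


def _depth_track_cm(seq: WalkingSequence, name: str) -> np.ndarray:
    """Temporal depth track of one keypoint, in cm (NaN where void)."""
    track = seq.keypoints[name]
    mm = np.array(
        [_keypoint_depth(seq.depth_stack[t], track[t]) for t in range(seq.n_frames)]
    )
    return mm / 10.0


def back_curvature(seq: WalkingSequence) -> float:
    """BC: max per-frame sagittal curvature of the spine triple (1/cm).

    Per frame the withers, lumbar and sacral tuber are mapped to
    sagittal points (s_i, h_i): s_i the cumulative along-spine
    horizontal distance in cm, h_i the height above the floor derived
    from camera height minus depth.
    """
    depths = {n: _depth_track_cm(seq, n) for n in SPINE_NAMES}
    curvatures = []
    for t in range(seq.n_frames):
        h = [seq.camera_height_mm / 10.0 - depths[n][t] for n in SPINE_NAMES]
        if any(np.isnan(v) for v in h):
            continue
        pts_px = [seq.keypoints[n][t] for n in SPINE_NAMES]
        s = [0.0]
        for i in range(1, 3):
            step = np.linalg.norm(pts_px[i] - pts_px[i - 1])
            s.append(s[-1] + step * seq.scale_cm_per_px)
        try:
            curvatures.append(
                circumcircle_curvature((s[0], h[0]), (s[1], h[1]), (s[2], h[2]))
            )
        except ValueError:
            continue
    if not curvatures:
        raise ValueError("no frame has valid depth at all spine keypoints")
    return float(max(curvatures))


def split_left_right(
    mask: np.ndarray, withers: np.ndarray, lumbar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a body mask into left/right halves about the spine axis.

    The axis runs withers -> lumbar; pixels are assigned by the sign of
    the 2-D cross product (p2 - p1) x (q - p1).  Positive (and zero)
    cross products are labelled left.
    """
    p1 = np.asarray(withers, dtype=float)
    p2 = np.asarray(lumbar, dtype=float)
    axis = p2 - p1
    if np.linalg.norm(axis) < 1e-12:
        raise ValueError("withers and lumbar coincide: no spine axis")
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    ys, xs = np.mgrid[0:H, 0:W]
    cross = axis[0] * (ys - p1[1]) - axis[1] * (xs - p1[0])
    left = mask & (cross >= 0)
    right = mask & (cross < 0)
    return left, right


def flow_fields(
    frames: np.ndarray,
    radius: int = 4,
    num_warp: int = 10,
    gaussian: bool = True,
) -> np.ndarray:
    """Dense velocity fields between consecutive frames.

    Returns a (T-1, 2, H, W) array of (row, col) velocity components in
    px/frame, estimated with dense iterative Lucas-Kanade flow.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.max() > 1.5:  # 8-bit input
        frames = frames / 255.0
    flows = [
        optical_flow_ilk(
            frames[t], frames[t + 1], radius=radius, num_warp=num_warp,
            gaussian=gaussian,
        )
        for t in range(frames.shape[0] - 1)
    ]
    return np.stack(flows)


def movement_asymmetry_index(
    flows: np.ndarray,
    region_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> float:
    """MAI = |muL - muR| / (muL + muR) over accumulated flow magnitude.

    ``flows`` holds one (2, H, W) velocity field per frame pair and
    ``region_pairs`` the matching left/right masks.  Magnitudes are
    accumulated over the whole sequence before the ratio, so one index
    describes the sequence.  Returns 0 when there is no motion at all.
    """
    flows = np.asarray(flows, dtype=float)
    if flows.ndim == 3:
        flows = flows[None]
    if len(flows) == 0:
        raise ValueError("need at least one flow field")
    if len(region_pairs) != len(flows):
        raise ValueError("one (left, right) mask pair per flow field required")
    sum_l = sum_r = 0.0
    n_l = n_r = 0
    for flow, (left, right) in zip(flows, region_pairs):
        if not left.any() or not right.any():
            raise ValueError("empty left or right region")
        mag = np.hypot(flow[0], flow[1])
        sum_l += float(mag[left].sum())
        n_l += int(left.sum())
        sum_r += float(mag[right].sum())
        n_r += int(right.sum())
    mu_l = sum_l / n_l
    mu_r = sum_r / n_r
    if mu_l + mu_r == 0:
        return 0.0
    return float(abs(mu_l - mu_r) / (mu_l + mu_r))


def _range_over_time(values: np.ndarray) -> float:
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        raise ValueError("keypoint depth is void in every frame")
    return float(vals.max() - vals.min())


def vertical_oscillation_back(seq: WalkingSequence) -> float:
    """VOB: max temporal depth range among the three spine keypoints (cm)."""
    return max(
        _range_over_time(_depth_track_cm(seq, name)) for name in SPINE_NAMES
    )


def vertical_oscillation_head(seq: WalkingSequence) -> float:
    """VOH: temporal depth range at the poll (cm)."""
    return _range_over_time(_depth_track_cm(seq, "poll"))


def trunk_inclination(seq: WalkingSequence) -> float:
    """TI: max |left - right| depth difference of the paired landmarks (cm)."""
    pairs = (
        ("left_scapula", "right_scapula"),
        ("left_tuber_coxae", "right_tuber_coxae"),
    )
    best = 0.0
    for left, right in pairs:
        diff = _depth_track_cm(seq, left) - _depth_track_cm(seq, right)
        diff = diff[~np.isnan(diff)]
        if diff.size:
            best = max(best, float(np.abs(diff).max()))
    return best


def lateral_sway_amplitude(seq: WalkingSequence) -> float:
    """LSAS: max horizontal peak-to-valley excursion of three spine
    abscissae (scapula midpoint, lumbar, sacral tuber), in cm."""
    mid_scap = 0.5 * (
        seq.keypoints["left_scapula"][:, 0] + seq.keypoints["right_scapula"][:, 0]
    )
    tracks = (
        mid_scap,
        seq.keypoints["lumbar"][:, 0],
        seq.keypoints["sacral_tuber"][:, 0],
    )
    return max(
        float((x.max() - x.min()) * seq.scale_cm_per_px) for x in tracks
    )


def _mai_from_sequence(
    seq: WalkingSequence,
    floor_depth_mm: float,
    min_height_mm: float,
    flow_radius: int,
) -> float:
    flows = flow_fields(seq.frames, radius=flow_radius)
    pairs = []
    for t in range(seq.n_frames - 1):
        body = foreground_mask(
            seq.depth_stack[t], floor_depth_mm, min_height_mm
        )
        pairs.append(
            split_left_right(
                body, seq.keypoints["withers"][t], seq.keypoints["lumbar"][t]
            )
        )
    return movement_asymmetry_index(flows, pairs)


def extract_all(
    seq: WalkingSequence,
    floor_depth_mm: float = 2500.0,
    min_height_mm: float = 300.0,
    flow_radius: int = 4,
) -> GaitFeatureVector:
    """Compute the six-feature vector of one sequence.

    MAI needs textured frames; when the sequence has none it is reported
    as ``None`` (flagged absent) and the depth/coordinate features are
    still computed.  Per-feature failures are re-raised with the feature
    name attached.
    """
    results: dict[str, float | None] = {}
    extractors = {
        "BC": lambda: back_curvature(seq),
        "VOB": lambda: vertical_oscillation_back(seq),
        "VOH": lambda: vertical_oscillation_head(seq),
        "TI": lambda: trunk_inclination(seq),
        "LSAS": lambda: lateral_sway_amplitude(seq),
    }
    for name, fn in extractors.items():
        try:
            results[name] = fn()
        except ValueError as exc:
            raise ValueError(f"{name}: {exc}") from exc
    if seq.frames is None:
        warnings.warn("sequence has no textured frames; MAI flagged absent")
        results["MAI"] = None
    else:
        try:
            results["MAI"] = _mai_from_sequence(
                seq, floor_depth_mm, min_height_mm, flow_radius
            )
        except ValueError as exc:
            raise ValueError(f"MAI: {exc}") from exc
    return GaitFeatureVector(
        bc=results["BC"],
        mai=results["MAI"],
        vob=results["VOB"],
        voh=results["VOH"],
        ti=results["TI"],
        lsas=results["LSAS"],
    )


def extract_table(sequences, **kwargs):
    """Extract features for many sequences into a tidy DataFrame."""
    import pandas as pd

    rows = []
    for seq in sequences:
        vec = extract_all(seq, **kwargs)
        row = {"sequence_id": seq.sequence_id, "label": seq.label}
        row.update(vec.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
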