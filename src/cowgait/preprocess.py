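"""Depth-frame cleaning for overhead cow recordings.

Raw structured-light depth maps carry range noise, isolated outliers and
void (zero) pixels where the sensor got no return.  The cleaning chain is

    clip -> bilateral filter -> 3x3 median -> nearest-neighbour hole fill

applied per frame, with a void-rate screen that rejects sequences whose
body region is too incomplete to trust.  All functions operate on 2-D
float arrays in millimetres where the value ``0`` encodes a void pixel.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "clip_depth",
    "denoise_depth",
    "fill_holes_nearest",
    "void_rate",
    "sequence_passes_void_screen",
    "foreground_mask",
    "depth_to_gray",
    "preprocess_frame",
    "preprocess_stack",
]

CLIP_MIN_MM = 1200.0
CLIP_MAX_MM = 2600.0
VOID_THRESHOLD = 0.10


def valid_mask(frame: np.ndarray) -> np.ndarray:
    """Boolean mask of non-void pixels (value > 0)."""
    return np.asarray(frame) > 0


def clip_depth(
    frame: np.ndarray,
    clip_min: float = CLIP_MIN_MM,
    clip_max: float = CLIP_MAX_MM,
) -> np.ndarray:
    """Mark depths outside the closed interval [clip_min, clip_max] as void.

    In-range values are returned unchanged; the interval boundaries are
    inclusive.
    """
    if not clip_min < clip_max:
        raise ValueError("clip_min must be smaller than clip_max")
    frame = np.asarray(frame, dtype=float)
    out = frame.copy()
    out[(frame < clip_min) | (frame > clip_max)] = 0.0
    return out


def denoise_depth(
    frame: np.ndarray,
    sigma_spatial: float = 5.0,
    sigma_range: float = 0.1,
    clip_min: float = CLIP_MIN_MM,
    clip_max: float = CLIP_MAX_MM,
    truncate: float = 2.0,
    median_win: int = 3,
) -> np.ndarray:
    """Bilateral filter followed by a masked median filter.

    The bilateral range kernel operates on depth normalised to [0, 1]
    over the clip span, so ``sigma_range`` is unitless (0.1 of the span
    by default).  Void pixels are excluded from both kernels and remain
    void in the output; hole filling is a separate stage.
    """
    frame = np.asarray(frame, dtype=float)
    bil = _masked_bilateral(
        frame,
        sigma_spatial=sigma_spatial,
        sigma_range_mm=sigma_range * (clip_max - clip_min),
        truncate=truncate,
    )
    return _masked_median(bil, win=median_win)


def _masked_bilateral(
    frame: np.ndarray,
    sigma_spatial: float,
    sigma_range_mm: float,
    truncate: float,
) -> np.ndarray:
    mask = valid_mask(frame)
    radius = int(math.ceil(truncate * sigma_spatial))
    H, W = frame.shape
    acc = np.zeros_like(frame)
    wacc = np.zeros_like(frame)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            w_s = math.exp(-(dy * dy + dx * dx) / (2.0 * sigma_spatial**2))
            vals, ok = _shift(frame, mask, dy, dx)
            w = w_s * np.exp(
                -((vals - frame) ** 2) / (2.0 * sigma_range_mm**2)
            )
            w *= ok
            acc += w * vals
            wacc += w
    out = np.zeros_like(frame)
    np.divide(acc, wacc, out=out, where=mask & (wacc > 0))
    return out


def _shift(
    frame: np.ndarray, mask: np.ndarray, dy: int, dx: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shift frame/mask by (dy, dx); out-of-frame pixels are invalid."""
    H, W = frame.shape
    vals = np.zeros_like(frame)
    ok = np.zeros_like(mask)
    ys = slice(max(0, -dy), min(H, H - dy))
    yd = slice(max(0, dy), min(H, H + dy))
    xs = slice(max(0, -dx), min(W, W - dx))
    xd = slice(max(0, dx), min(W, W + dx))
    vals[yd, xd] = frame[ys, xs]
    ok[yd, xd] = mask[ys, xs]
    return vals, ok


def _masked_median(frame: np.ndarray, win: int = 3) -> np.ndarray:
    if win % 2 != 1:
        raise ValueError("median window must be odd")
    mask = valid_mask(frame)
    r = win // 2
    stack = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            vals, ok = _shift(frame, mask, dy, dx)
            vals = vals.copy()
            vals[~ok] = np.nan
            stack.append(vals)
    stacked = np.stack(stack)
    with np.errstate(all="ignore"):
        med = np.nanmedian(stacked, axis=0)
    out = np.zeros_like(frame)
    out[mask] = med[mask]
    return out


def fill_holes_nearest(frame: np.ndarray) -> np.ndarray:
    """Fill every void pixel with the value of its nearest valid pixel.

    Nearest is Euclidean in pixel coordinates; exact distance ties are
    broken by the lexicographically smallest (row, column), so the
    result is fully deterministic.  Raises if the frame has no valid
    pixel at all.
    """
    frame = np.asarray(frame, dtype=float)
    mask = valid_mask(frame)
    if not mask.any():
        raise ValueError("cannot fill an all-void frame")
    if mask.all():
        return frame.copy()
    valid_rc = np.argwhere(mask)  # already sorted lexicographically
    void_rc = np.argwhere(~mask)
    tree = cKDTree(valid_rc)
    dist, idx = tree.query(void_rc, k=1)
    # enforce the lexicographic tie-break among equidistant valid pixels
    groups = tree.query_ball_point(void_rc, r=dist + 1e-9)
    for j, cands in enumerate(groups):
        if len(cands) > 1:
            d = np.linalg.norm(valid_rc[cands] - void_rc[j], axis=1)
            tied = [c for c, dd in zip(cands, d) if dd <= dist[j] + 1e-9]
            idx[j] = min(tied)
    out = frame.copy()
    out[void_rc[:, 0], void_rc[:, 1]] = frame[
        valid_rc[idx, 0], valid_rc[idx, 1]
    ]
    return out


def void_rate(frame: np.ndarray, body_mask: np.ndarray) -> float:
    """Fraction of void pixels inside the body region."""
    body_mask = np.asarray(body_mask, dtype=bool)
    n = int(body_mask.sum())
    if n == 0:
        raise ValueError("body mask is empty")
    voids = int(((np.asarray(frame) == 0) & body_mask).sum())
    return voids / n


def sequence_passes_void_screen(
    stack: np.ndarray,
    body_masks: np.ndarray,
    threshold: float = VOID_THRESHOLD,
) -> bool:
    """Sequence screening rule: reject when any frame's body-region void
    rate is greater than or equal to ``threshold`` (boundary inclusive)."""
    for frame, mask in zip(stack, body_masks):
        if void_rate(frame, mask) >= threshold:
            return False
    return True


def foreground_mask(
    frame: np.ndarray,
    floor_depth_mm: float = 2500.0,
    min_height_mm: float = 300.0,
) -> np.ndarray:
    """Segment the cow body as pixels standing above the floor plane.

    Keeps valid pixels with depth < floor - min_height and retains only
    the largest connected component.  Raises when no pixel qualifies,
    signalling that no animal is present.
    """
    frame = np.asarray(frame, dtype=float)
    cand = valid_mask(frame) & (frame < floor_depth_mm - min_height_mm)
    if not cand.any():
        raise ValueError("no foreground: frame contains no animal")
    labels, n = ndimage.label(cand)
    if n == 1:
        return cand
    sizes = ndimage.sum_labels(cand, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return labels == keep


def depth_to_gray(
    frame: np.ndarray,
    clip_min: float = CLIP_MIN_MM,
    clip_max: float = CLIP_MAX_MM,
) -> np.ndarray:
    """Linearly map [clip_min, clip_max] to 8-bit gray, rounding half-up."""
    frame = np.asarray(frame, dtype=float)
    scaled = 255.0 * (frame - clip_min) / (clip_max - clip_min)
    gray = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
    return gray.astype(np.uint8)


def preprocess_frame(
    frame: np.ndarray,
    clip_min: float = CLIP_MIN_MM,
    clip_max: float = CLIP_MAX_MM,
    sigma_spatial: float = 5.0,
    sigma_range: float = 0.1,
    median_win: int = 3,
    truncate: float = 2.0,
) -> np.ndarray:
    """Full cleaning chain: clip -> bilateral -> median -> hole fill."""
    out = clip_depth(frame, clip_min, clip_max)
    out = denoise_depth(
        out,
        sigma_spatial=sigma_spatial,
        sigma_range=sigma_range,
        clip_min=clip_min,
        clip_max=clip_max,
        truncate=truncate,
        median_win=median_win,
    )
    return fill_holes_nearest(out)


def preprocess_stack(stack: np.ndarray, **kwargs) -> np.ndarray:
    """Apply :func:`preprocess_frame` to every frame of a (T, H, W) stack."""
    return np.stack([preprocess_frame(f, **kwargs) for f in stack])
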