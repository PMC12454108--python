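"""Class-conditional synthetic walking sequences.

The farm recordings behind the published class means are not deposited,
so every downstream stage is exercised on simulated sequences whose
extracted features hit configurable targets.  The generator lays the
eight back keypoints on a fixed anatomical template walking down the
image, renders depth frames carrying a static spinal arch (back
curvature), sinusoidal vertical oscillations (back and head), left-right
depth imbalance (trunk inclination) and lateral sway, and renders
textured frame pairs whose two body halves translate at different
speeds so dense optical flow recovers the target movement asymmetry.

Sampled sinusoids are rescaled so the discrete frames attain the exact
peak-to-peak target, which makes noise-free round-trips through the
feature extractors exact to floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES
from .sequences import CLASS_LABELS, SimulatedSequence

__all__ = [
    "PUBLISHED_CLASS_MEANS",
    "GaitClassParams",
    "class_params",
    "sample_feature_vectors",
    "sample_dataset",
    "arch_sag_for_curvature",
    "simulate_sequence",
]

#: Published per-class mean values of the six gait features
#: (BC 1/cm, MAI unitless, VOB/VOH/TI/LSAS cm).
PUBLISHED_CLASS_MEANS: dict[str, dict[str, float]] = {
    "sound": {
        "BC": 0.00021, "MAI": 0.012, "VOB": 4.72,
        "VOH": 7.92, "TI": 3.63, "LSAS": 5.33,
    },
    "mild": {
        "BC": 0.00054, "MAI": 0.027, "VOB": 8.23,
        "VOH": 10.36, "TI": 5.18, "LSAS": 6.67,
    },
    "severe": {
        "BC": 0.00093, "MAI": 0.064, "VOB": 12.90,
        "VOH": 17.28, "TI": 6.76, "LSAS": 9.18,
    },
}

#: Default within-class coefficient of variation.  The source tables give
#: class means only; 0.15 reproduces the qualitative between-class overlap
#: seen in the published box plots and is an artifact choice.
DEFAULT_CV = 0.15


@dataclass
class GaitClassParams:
    """Targets and geometry for one severity class.

    ``target_means`` maps feature name to the class mean; ``target_cv``
    is the per-feature coefficient of variation of the truncated-normal
    noise model (a scalar applies to every feature).
    """

    class_label: str
    target_means: dict[str, float]
    target_cv: dict[str, float] = field(default_factory=dict)
    n_frames: int = 64
    fps: float = 30.0
    stride_freq_hz: float = 1.0
    chord_cm: float = 120.0
    # rendering geometry
    frame_height: int = 160
    frame_width: int = 96
    scale_cm_per_px: float = 1.25
    camera_height_mm: float = 3200.0
    floor_depth_mm: float = 2500.0
    back_depth_mm: float = 1800.0
    poll_depth_mm: float = 2000.0
    base_flow_speed_px: float = 2.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for name in FEATURE_NAMES:
            if name not in self.target_means:
                raise ValueError(f"target mean missing for {name}")
            if self.target_means[name] < 0:
                raise ValueError(f"target mean for {name} must be >= 0")
        if not 0 <= self.target_means["MAI"] < 1:
            raise ValueError("MAI mean must lie in [0, 1)")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if isinstance(self.target_cv, (int, float)):
            self.target_cv = {n: float(self.target_cv) for n in FEATURE_NAMES}
        for name in FEATURE_NAMES:
            self.target_cv.setdefault(name, DEFAULT_CV)
            if self.target_cv[name] < 0:
                raise ValueError("coefficient of variation must be >= 0")
        if self.chord_cm <= 0:
            raise ValueError("chord_cm must be positive")


def class_params(label: str, cv: float | dict = DEFAULT_CV, **overrides) -> GaitClassParams:
    """Parameters for one severity class with the published mean targets."""
    return GaitClassParams(
        class_label=label,
        target_means=dict(PUBLISHED_CLASS_MEANS[label]),
        target_cv=cv if isinstance(cv, dict) else float(cv),
        **overrides,
    )


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, cv: float, upper: float, n: int
) -> np.ndarray:
    if cv == 0 or mean == 0:
        return np.full(n, mean)
    sd = cv * mean
    a = (0.0 - mean) / sd
    b = (upper - mean) / sd if np.isfinite(upper) else np.inf
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_feature_vectors(
    params: GaitClassParams, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` labelled six-feature rows from the class noise model.

    Each feature is an independent normal truncated at zero (and at one
    for MAI) with the class target mean and coefficient of variation;
    ``cv = 0`` collapses to the exact class means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {
        name: _truncnorm_draw(
            rng,
            params.target_means[name],
            params.target_cv[name],
            upper=1.0 if name == "MAI" else np.inf,
            n=n,
        )
        for name in FEATURE_NAMES
    }
    df = pd.DataFrame(data)
    df.insert(0, "label", params.class_label)
    return df


def sample_dataset(
    n_per_class: dict[str, int],
    seed: int,
    cv: float | dict = DEFAULT_CV,
    means: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Feature table over several classes (shortcut for classifier studies)."""
    ss = np.random.SeedSequence(seed)
    frames = []
    for label, child in zip(sorted(n_per_class), ss.spawn(len(n_per_class))):
        p = class_params(label, cv=cv)
        if means is not None:
            p.target_means = dict(means[label])
        frames.append(
            sample_feature_vectors(
                p, n_per_class[label], int(child.generate_state(1)[0] % 2**31)
            )
        )
    return pd.concat(frames, ignore_index=True)


def screening_benchmark_table(
    n: int,
    seed: int,
    n_strong: int = 3,
    n_weak: int = 1,
    n_null: int = 2,
    strong_shift: float = 1.2,
    weak_shift: float = 0.3,
) -> pd.DataFrame:
    """Feature table with known ground truth for screening studies.

    Emulates the qualitative pattern of the published screening table:
    a few strongly class-separated features, one weakly separated, and
    pure-noise features.  Rows are split evenly over the three severity
    classes; feature j of a class with index c is N(shift_j * (c - 1), 1).
    Columns are named strong0..., weak0..., null0...
    """
    if n < 3:
        raise ValueError("need at least one row per class")
    rng = np.random.default_rng(seed)
    labels = np.array(
        [CLASS_LABELS[i % 3] for i in range(n)]
    )
    class_index = np.array([CLASS_LABELS.index(lbl) - 1 for lbl in labels])
    cols: dict[str, np.ndarray] = {}
    for j in range(n_strong):
        cols[f"strong{j}"] = rng.normal(strong_shift * class_index, 1.0)
    for j in range(n_weak):
        cols[f"weak{j}"] = rng.normal(weak_shift * class_index, 1.0)
    for j in range(n_null):
        cols[f"null{j}"] = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame(cols)
    df.insert(0, "label", labels)
    return df


def arch_sag_for_curvature(k_target: float, chord_cm: float) -> float:
    """Mid-chord sag of a circular arc with the requested curvature.

    Inverts the circumcircle geometry: endpoints at height 0 separated
    by the chord L and a midpoint raised by the sag d lie on a circle of
    radius R = L^2 / (8 d) + d / 2.  Returns the smaller root of
    d^2 - 2 R d + L^2 / 4 = 0 for R = 1 / k_target; zero curvature means
    a straight spine (d = 0).
    """
    if k_target < 0:
        raise ValueError("curvature must be >= 0")
    if chord_cm <= 0:
        raise ValueError("chord must be positive")
    if k_target == 0:
        return 0.0
    radius = 1.0 / k_target
    disc = radius * radius - chord_cm * chord_cm / 4.0
    if disc < 0:
        raise ValueError(
            "no circle of curvature "
            f"{k_target} passes through a chord of {chord_cm} cm"
        )
    return radius - math.sqrt(disc)


def _pp_signal(
    n: int, freq_hz: float, fps: float, phase: float, peak_to_peak: float
) -> np.ndarray:
    """Sampled sinusoid rescaled to attain the exact peak-to-peak target."""
    if peak_to_peak == 0:
        return np.zeros(n)
    raw = np.cos(2.0 * np.pi * freq_hz * np.arange(n) / fps + phase)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        raw = np.linspace(-1.0, 1.0, n)
        lo, hi = -1.0, 1.0
    return (raw - lo) / (hi - lo) * peak_to_peak - peak_to_peak / 2.0


def _unit_signal(n: int, freq_hz: float, fps: float, phase: float) -> np.ndarray:
    """Sampled sinusoid rescaled to span exactly [-1, 1]."""
    sig = _pp_signal(n, freq_hz, fps, phase, 2.0)
    return sig


def _template_positions(chord_cm: float) -> dict[str, tuple[float, float]]:
    """(s, lateral) cm for each keypoint; s measured from the withers."""
    return {
        "poll": (-30.0, 0.0),
        "withers": (0.0, 0.0),
        "left_scapula": (15.0, +18.0),
        "right_scapula": (15.0, -18.0),
        "lumbar": (chord_cm / 2.0, 0.0),
        "left_tuber_coxae": (chord_cm - 20.0, +16.0),
        "right_tuber_coxae": (chord_cm - 20.0, -16.0),
        "sacral_tuber": (chord_cm, 0.0),
    }


def _bandlimited_texture(
    rng: np.random.Generator, shape: tuple[int, int]
) -> np.ndarray:
    """Smooth checker plus band-limited speckle, periodic, in [0, 1]."""
    H, W = shape
    noise = rng.normal(size=shape)
    F = np.fft.fft2(noise)
    ky = np.fft.fftfreq(H)[:, None]
    kx = np.fft.fftfreq(W)[None, :]
    F *= np.exp(-(np.hypot(ky, kx) / 0.06) ** 2)
    speckle = np.real(np.fft.ifft2(F))
    speckle = (speckle - speckle.min()) / (speckle.max() - speckle.min() + 1e-12)
    ys, xs = np.mgrid[0:H, 0:W]
    checker = 0.5 + 0.5 * np.sin(2 * np.pi * ys / 16.0) * np.sin(
        2 * np.pi * xs / 16.0
    )
    tex = 0.65 * speckle + 0.35 * checker
    return (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)


def _scroll_rows(texture: np.ndarray, shift_px: float) -> np.ndarray:
    """Exact periodic subpixel translation along rows via FFT phase."""
    H = texture.shape[0]
    F = np.fft.fft(texture, axis=0)
    phase = np.exp(-2j * np.pi * np.fft.fftfreq(H)[:, None] * shift_px)
    return np.real(np.fft.ifft(F * phase, axis=0))


def simulate_sequence(params: GaitClassParams, seed: int) -> SimulatedSequence:
    """Render one walking sequence realising per-sequence feature targets.

    The sequence targets are drawn from the class noise model (exactly
    the class means when ``cv = 0``); the rendered depth stack, keypoint
    tracks and textured frames realise them analytically, so noise-free
    extraction round-trips are exact for the depth/coordinate features.
    """
    ss = np.random.SeedSequence(seed)
    s_targets, s_texture = ss.spawn(2)
    row = sample_feature_vectors(
        params, 1, int(s_targets.generate_state(1)[0] % 2**31)
    ).iloc[0]
    targets = {name: float(row[name]) for name in FEATURE_NAMES}

    T = params.n_frames
    H, W = params.frame_height, params.frame_width
    scale = params.scale_cm_per_px
    cx = W / 2.0
    positions = _template_positions(params.chord_cm)

    # gait signals (peak-to-peak / unit-amplitude, exact at the samples)
    osc_back_mm = _pp_signal(
        T, params.stride_freq_hz, params.fps, 0.0, 10.0 * targets["VOB"]
    )
    osc_head_mm = _pp_signal(
        T, params.stride_freq_hz, params.fps, np.pi / 3.0, 10.0 * targets["VOH"]
    )
    tilt_unit = _unit_signal(T, params.stride_freq_hz, params.fps, np.pi / 5.0)
    tilt_rear_unit = _unit_signal(
        T, params.stride_freq_hz, params.fps, np.pi / 2.5
    )
    sway_px = _pp_signal(
        T, params.stride_freq_hz / 2.0, params.fps, np.pi / 7.0,
        targets["LSAS"] / scale,
    )

    sag_cm = arch_sag_for_curvature(targets["BC"], params.chord_cm)

    # walking translation down the image
    template_len_px = (params.chord_cm + 30.0) / scale
    avail = H - 8.0 - template_len_px
    if avail < 0:
        raise ValueError("template does not fit image bounds")
    speed = min(1.0, avail / max(T - 1, 1))

    tracks: dict[str, np.ndarray] = {}
    t_idx = np.arange(T)
    y_front = 4.0 + template_len_px + speed * t_idx
    for name, (s_cm, lat_cm) in positions.items():
        y = y_front - (s_cm + 30.0) / scale
        x = cx + lat_cm / scale + sway_px
        tracks[name] = np.stack([x, np.asarray(y, dtype=float)], axis=1)

    # per-frame keypoint depths, mm
    d0 = params.back_depth_mm
    kp_depth = {
        "withers": d0 - osc_back_mm,
        "lumbar": d0 - 10.0 * sag_cm - osc_back_mm,
        "sacral_tuber": d0 - osc_back_mm,
        "poll": params.poll_depth_mm - osc_head_mm,
        "left_scapula": d0 + 50.0 + 5.0 * targets["TI"] * tilt_unit,
        "right_scapula": d0 + 50.0 - 5.0 * targets["TI"] * tilt_unit,
        "left_tuber_coxae": d0 + 40.0 + 3.0 * targets["TI"] * tilt_rear_unit,
        "right_tuber_coxae": d0 + 40.0 - 3.0 * targets["TI"] * tilt_rear_unit,
    }

    # bounds check before rendering
    for name, track in tracks.items():
        if (
            track[:, 0].min() < 2 or track[:, 0].max() > W - 3
            or track[:, 1].min() < 2 or track[:, 1].max() > H - 3
        ):
            raise ValueError("template does not fit image bounds")

    depth = np.full((T, H, W), params.floor_depth_mm, dtype=float)
    ys, xs = np.mgrid[0:H, 0:W]
    body_half_len = params.chord_cm / 2.0 / scale + 10.0
    body_half_wid = 30.0 / scale
    for t in range(T):
        y_mid = 0.5 * (tracks["withers"][t, 1] + tracks["sacral_tuber"][t, 1])
        x_mid = cx + sway_px[t]
        body = (
            ((ys - y_mid) / body_half_len) ** 2
            + ((xs - x_mid) / body_half_wid) ** 2
        ) <= 1.0
        depth[t][body] = d0
        head = (ys - tracks["poll"][t, 1]) ** 2 + (
            xs - tracks["poll"][t, 0]
        ) ** 2 <= 8.0**2
        depth[t][head] = params.poll_depth_mm
        # constant 5x5 patches make the 3x3-median keypoint lookup exact
        for name, track in tracks.items():
            px = int(round(track[t, 0]))
            py = int(round(track[t, 1]))
            depth[t][py - 2 : py + 3, px - 2 : px + 3] = kp_depth[name][t]

    # textured frames: two half-frame textures scrolled at different
    # speeds so flow-based MAI approximates the target
    rng_tex = np.random.default_rng(s_texture)
    tex_left = _bandlimited_texture(rng_tex, (H, W))
    tex_right = _bandlimited_texture(rng_tex, (H, W))
    m = targets["MAI"]
    c = params.base_flow_speed_px
    v_left, v_right = c * (1.0 + m), c * (1.0 - m)
    col_left = xs >= cx  # image +x is the animal's left when walking +y
    frames = np.empty((T, H, W), dtype=np.uint8)
    for t in range(T):
        fl = _scroll_rows(tex_left, v_left * t)
        fr = _scroll_rows(tex_right, v_right * t)
        combined = np.where(col_left, fl, fr)
        frames[t] = np.clip(np.round(combined * 255.0), 0, 255).astype(np.uint8)

    return SimulatedSequence(
        depth_stack=depth,
        keypoints=tracks,
        frames=frames,
        scale_cm_per_px=scale,
        camera_height_mm=params.camera_height_mm,
        fps=params.fps,
        label=params.class_label,
        sequence_id=f"{params.class_label}-{seed}",
        targets=targets,
    )
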