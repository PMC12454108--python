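"""One declarative configuration document for the whole pipeline.

Defaults follow the published acquisition and analysis settings where
one exists (depth clip range 1200-2600 mm, bilateral s = 5 / r = 0.1,
3x3 median, 10% void screening, B = 50 permutations, FDR alpha = 0.05,
8:2 stratified split); everything else is a documented package choice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import FUSION_SUBSETS
from .features import FEATURE_NAMES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # depth preprocessing
    clip_min: float = 1200.0
    clip_max: float = 2600.0
    bilateral_s: float = 5.0
    bilateral_r: float = 0.1
    bilateral_truncate: float = 2.0
    median_win: int = 3
    void_threshold: float = 0.10  # per-frame max rule (strict reading)
    floor_depth_mm: float = 2500.0
    min_height_mm: float = 300.0
    # optical flow
    flow_radius: int = 4
    # simulation
    n_frames: int = 64
    fps: float = 30.0
    stride_freq_hz: float = 1.0
    chord_cm: float = 120.0
    cv: float = 0.15  # within-class CV: artifact choice, means-only source
    n_sequences_demo: int = 6
    n_samples_per_class: dict = field(
        default_factory=lambda: {"sound": 260, "mild": 237, "severe": 244}
    )
    # screening
    screen_B: int = 50
    screen_alpha: float = 0.05
    screen_trees: int = 500
    # classification
    rf_trees: int = 500
    knn_k: int = 5
    svm_c: float = 1.0
    test_frac: float = 0.2
    subsets: list = field(default_factory=lambda: [list(s) for s in FUSION_SUBSETS])
    algos: list = field(default_factory=lambda: ["RF", "KNN", "SVM"])
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if not self.clip_min < self.clip_max:
            raise ValueError("clip_min must be below clip_max")
        if not 0 < self.void_threshold <= 1:
            raise ValueError("void_threshold must be in (0, 1]")
        for subset in self.subsets:
            unknown = [f for f in subset if f not in FEATURE_NAMES]
            if unknown:
                raise ValueError(f"unknown feature name(s) in subsets: {unknown}")
        for algo in self.algos:
            if algo not in ("RF", "KNN", "SVM"):
                raise ValueError(f"unknown algorithm {algo!r}")

    def to_yaml(self, path: Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cfg = cls(**doc)
        cfg.validate()
        return cfg
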