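"""Unbiased feature screening: Gini importance + permutation correction.

Tree-based impurity importances are biased estimators of relevance, so
raw Gini rankings are corrected with a permutation importance (PIMP)
null: the class labels are permuted B times, the forest refit each
time, and the observed importance of each feature is compared against
its null distribution through a right-tail permutation p-value.  The
per-feature p-values are then controlled for the false discovery rate
with the Benjamini-Hochberg step-up procedure; a feature is retained
when its adjusted p-value falls below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ScreeningResult",
    "gini_importance",
    "pimp_null",
    "pimp_pvalue",
    "bh_adjust",
    "kruskal_pvalues",
    "screen_features",
]

DEFAULT_N_TREES = 500
DEFAULT_B = 50
DEFAULT_ALPHA = 0.05


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D feature table")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes")
    return X, y


def gini_importance(
    X, y, n_trees: int = DEFAULT_N_TREES, seed: int = 0, max_features="sqrt"
) -> np.ndarray:
    """Mean-impurity-decrease importances of a random forest.

    Returned importances are normalised to sum to one across features
    (the forest normalisation); the result is deterministic per seed.
    ``max_features=None`` searches every feature at each split, making
    the importances exactly equivariant under column permutation.
    """
    X, y = _as_xy(X, y)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(seed) % 2**31,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest.feature_importances_


def pimp_null(
    X, y, B: int = DEFAULT_B, seed: int = 0, n_trees: int = DEFAULT_N_TREES
) -> np.ndarray:
    """B x d matrix of importances under label permutation.

    Row b is the Gini importance vector of a forest refit on labels
    permuted with the b-th substream of the master seed; each refit also
    gets a fresh derived forest seed.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    X, y = _as_xy(X, y)
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(B):
        perm_seed, forest_seed = child.generate_state(2) % 2**31
        perm = np.random.default_rng(perm_seed).permutation(len(y))
        rows.append(gini_importance(X, y[perm], n_trees=n_trees, seed=forest_seed))
    return np.vstack(rows)


def pimp_pvalue(observed: float, null: np.ndarray) -> float:
    """Right-tail permutation p-value with add-one smoothing.

    p = (1 + #{null_b >= observed}) / (1 + B); ties count as >=, so an
    observed value equal to every null value gives p = 1.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 1:
        raise ValueError("empty null distribution")
    return float((1 + int((null >= observed).sum())) / (1 + null.size))


def bh_adjust(
    p_raw, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and retention flags.

    Returns ``(p_adj, retained)`` where ``retained[i]`` is True iff
    ``p_adj[i] < alpha`` (strictly below, matching the screening rule).
    """
    p = np.asarray(p_raw, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    d = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * d / np.arange(1, d + 1)
    # enforce monotonicity from the largest rank downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    p_adj = np.empty_like(adj)
    p_adj[order] = adj
    return p_adj, p_adj < alpha


def kruskal_pvalues(X, y) -> np.ndarray:
    """Per-feature Kruskal-Wallis p-values across the class groups.

    Reported as the between-group significance column of the screening
    table; never used for retention.
    """
    X, y = _as_xy(X, y)
    groups = [X[y == lbl] for lbl in np.unique(y)]
    out = []
    for j in range(X.shape[1]):
        samples = [g[:, j] for g in groups]
        if all(np.ptp(s) == 0 for s in samples):
            out.append(1.0)
            continue
        out.append(stats.kruskal(*samples).pvalue)
    return np.asarray(out)


@dataclass
class ScreeningResult:
    """Per-feature screening outcome plus the run configuration."""

    feature_names: list[str]
    gini: np.ndarray
    null_importances: np.ndarray  # (B, d)
    p_raw: np.ndarray
    p_adj: np.ndarray
    retained: np.ndarray
    kruskal_p: np.ndarray
    B: int
    alpha: float
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def retained_features(self) -> list[str]:
        return [n for n, r in zip(self.feature_names, self.retained) if r]

    def to_frame(self) -> pd.DataFrame:
        """Screening report with one row per feature."""
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "intergroup_p": self.kruskal_p,
                "gini_importance": self.gini,
                "pimp_p_raw": self.p_raw,
                "pimp_p_adj": self.p_adj,
                "retained": self.retained,
            }
        )


def screen_features(
    X,
    y,
    feature_names: list[str] | None = None,
    B: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> ScreeningResult:
    """Full screening chain: Gini -> PIMP null -> p-values -> BH.

    The result is a pure function of ``(X, y, B, alpha, seed, n_trees)``.
    """
    X, y = _as_xy(X, y)
    d = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(d)]
    if len(feature_names) != d:
        raise ValueError("feature_names length mismatch")
    ss = np.random.SeedSequence(seed)
    obs_seed, null_seed = (int(s) for s in ss.generate_state(2) % 2**31)
    gini = gini_importance(X, y, n_trees=n_trees, seed=obs_seed)
    null = pimp_null(X, y, B=B, seed=null_seed, n_trees=n_trees)
    p_raw = np.array(
        [pimp_pvalue(gini[j], null[:, j]) for j in range(d)]
    )
    p_adj, retained = bh_adjust(p_raw, alpha=alpha)
    return ScreeningResult(
        feature_names=list(feature_names),
        gini=gini,
        null_importances=null,
        p_raw=p_raw,
        p_adj=p_adj,
        retained=retained,
        kruskal_p=kruskal_pvalues(X, y),
        B=B,
        alpha=alpha,
        seed=seed,
    )
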