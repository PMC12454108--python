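"""Forward mathematics of the keypoint-detector building blocks.

Pure-numpy, desk-testable forward passes of the bespoke network pieces:
windowed adaptive sparse self-attention (dense softmax attention fused
with squared-ReLU sparse attention), the feature-refinement feedforward
network (expand, split, depthwise-gate, project), and adaptive graph
convolution over the 8-keypoint cow skeleton with fixed, learnable and
data-driven adjacency terms.  No training — these exist so the module
arithmetic can be property-tested against straight-line oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .sequences import KEYPOINT_NAMES

__all__ = [
    "WindowTokens",
    "FRFNParams",
    "AGCParams",
    "gelu",
    "softmax_rows",
    "assa_forward",
    "frfn_forward",
    "normalize_adjacency",
    "data_driven_graph",
    "agc_forward",
    "cow_skeleton_edges",
    "cow_skeleton_subsets",
    "selfcheck",
]

EPS = 1e-6


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact Gaussian-error linear unit."""
    x = np.asarray(x, dtype=float)
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def softmax_rows(scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def relu_squared(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) ** 2


@dataclass
class WindowTokens:
    """Tokens of one non-overlapping M x M attention window.

    ``x`` holds the M^2 flattened tokens; the projections map channels
    to the attention dimension d, ``bias`` is the learnable position
    bias and ``fusion_logits`` the two scalars whose softmax weights the
    dense and sparse branches.
    """

    x: np.ndarray  # (M^2, C)
    w_q: np.ndarray  # (C, d)
    w_k: np.ndarray
    w_v: np.ndarray
    bias: np.ndarray  # (M^2, M^2)
    fusion_logits: np.ndarray = field(
        default_factory=lambda: np.zeros(2)
    )


def assa_forward(tokens: WindowTokens) -> np.ndarray:
    """Adaptive sparse self-attention over one window.

    DSA applies row-softmax to the scaled scores QK^T/sqrt(d) + B; SSA
    applies squared ReLU to the same scores and normalises each row by
    its sum (rows whose scores are all non-positive stay exactly zero).
    The output is the convex fusion w1*DSA(V) + w2*SSA(V) with (w1, w2)
    the softmax of two learnable scalars.
    """
    x = np.asarray(tokens.x, dtype=float)
    n, C = x.shape
    for name, w in (("w_q", tokens.w_q), ("w_k", tokens.w_k), ("w_v", tokens.w_v)):
        if np.asarray(w).shape[0] != C:
            raise ValueError(f"{name} does not match the token channels")
    q = x @ tokens.w_q
    k = x @ tokens.w_k
    v = x @ tokens.w_v
    d = q.shape[1]
    if np.asarray(tokens.bias).shape != (n, n):
        raise ValueError("position bias must be (M^2, M^2)")
    scores = q @ k.T / np.sqrt(d) + tokens.bias
    dense = softmax_rows(scores) @ v
    sparse_w = relu_squared(scores)
    row_sums = sparse_w.sum(axis=1, keepdims=True)
    sparse_w = np.divide(
        sparse_w, row_sums, out=np.zeros_like(sparse_w), where=row_sums > 0
    )
    sparse = sparse_w @ v
    w1, w2 = softmax_rows(np.asarray(tokens.fusion_logits, dtype=float)[None, :])[0]
    return w1 * dense + w2 * sparse


@dataclass
class FRFNParams:
    """Weights of the feature-refinement feedforward network.

    Channel maps: ``w1`` expands C to 2C (split into two C halves),
    ``w2`` projects C back to C.  ``pconv`` is a 3x3 partial convolution
    over the first ``n_pconv`` channels; ``dw`` a 3x3 depthwise kernel
    per channel of the gating half.
    """

    w1: np.ndarray  # (2C, C)
    w2: np.ndarray  # (C, C)
    pconv: np.ndarray  # (n_pconv, n_pconv, 3, 3)
    dw: np.ndarray  # (C, 3, 3)
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None


def _conv2d_same(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """3x3 cross-correlation with zero padding (same spatial shape)."""
    return ndimage.correlate(plane, kernel, mode="constant", cval=0.0)


def frfn_forward(x: np.ndarray, params: FRFNParams) -> np.ndarray:
    """Enhance-then-simplify feedforward refinement of a feature map.

    ``x`` is (H, W, C).  Chain: partial 3x3 convolution on the leading
    channels -> linear expansion W1 -> GELU -> split channels in half ->
    depthwise 3x3 convolution of one half gates the other elementwise ->
    linear projection W2 -> GELU.  Spatial shape is preserved.
    """
    x = np.asarray(x, dtype=float)
    H, W, C = x.shape
    n_p = params.pconv.shape[0]
    if n_p > C:
        raise ValueError("partial convolution spans more channels than exist")
    xt = x.copy()
    for p in range(n_p):
        xt[:, :, p] = sum(
            _conv2d_same(x[:, :, q], params.pconv[p, q]) for q in range(n_p)
        )
    expanded = np.tensordot(xt, params.w1, axes=([2], [1]))  # (H, W, 2C)
    if params.b1 is not None:
        expanded = expanded + params.b1
    if expanded.shape[2] % 2 != 0:
        raise ValueError("expanded channel count must be even to split")
    xhat = gelu(expanded)
    half = expanded.shape[2] // 2
    x1, x2 = xhat[:, :, :half], xhat[:, :, half:]
    gated = np.empty_like(x2)
    for c in range(half):
        gated[:, :, c] = _conv2d_same(x2[:, :, c], params.dw[c])
    refined = x1 * gated
    out = np.tensordot(refined, params.w2, axes=([2], [1]))
    if params.b2 is not None:
        out = out + params.b2
    return gelu(out)


def normalize_adjacency(a_bar: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Symmetric degree normalisation L^-1/2 A L^-1/2 of a binary graph.

    Isolated nodes receive an epsilon degree so the normalisation stays
    defined; the result is symmetric whenever the input is.
    """
    a_bar = np.asarray(a_bar, dtype=float)
    if not np.isin(a_bar, (0.0, 1.0)).all():
        raise ValueError("adjacency entries must be binary")
    deg = a_bar.sum(axis=1)
    deg = np.where(deg > 0, deg, eps)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return inv_sqrt[:, None] * a_bar * inv_sqrt[None, :]


def data_driven_graph(
    x: np.ndarray, w_theta: np.ndarray, w_phi: np.ndarray
) -> np.ndarray:
    """Embedded-Gaussian similarity graph, row-normalised by softmax.

    ``x`` is (Cin, T, N); theta/phi are 1x1 channel maps Cin -> Ce.  The
    similarity of keypoints i and j is the inner product of their
    embedded (Ce x T) representations; softmax over j makes each row a
    distribution over source nodes.
    """
    x = np.asarray(x, dtype=float)
    theta = np.tensordot(w_theta, x, axes=([1], [0]))  # (Ce, T, N)
    phi = np.tensordot(w_phi, x, axes=([1], [0]))
    scores = np.einsum("eti,etj->ij", theta, phi)
    return softmax_rows(scores)


@dataclass
class AGCParams:
    """Per-subset weights of the adaptive graph convolution.

    One entry of each list per spatial subset k: a 1x1 channel map
    ``w[k]`` (Cout x Cin), a binary adjacency ``a_bar[k]``, a learnable
    offset ``b[k]`` (initialised to zero in training), and optional
    embedding maps for the data-driven graph (``None`` disables that
    term).  ``residual_w`` aligns channels when Cin != Cout.
    """

    w: list[np.ndarray]
    a_bar: list[np.ndarray]
    b: list[np.ndarray] | None = None
    w_theta: list[np.ndarray] | None = None
    w_phi: list[np.ndarray] | None = None
    residual_w: np.ndarray | None = None

    @property
    def n_subsets(self) -> int:
        return len(self.w)


def agc_forward(x: np.ndarray, params: AGCParams) -> np.ndarray:
    """Adaptive graph convolution Y = sum_k W_k X (A_k + B_k + C_k) + R(X).

    ``x`` is (Cin, T, N).  A_k is the symmetric-normalised fixed
    adjacency, B_k the learnable offset, C_k the data-driven softmax
    graph.  The residual R is the identity when Cin equals Cout,
    otherwise the provided 1x1 channel alignment.
    """
    x = np.asarray(x, dtype=float)
    cin, T, N = x.shape
    if len(params.a_bar) != params.n_subsets:
        raise ValueError("per-subset parameter lists differ in length")
    cout = params.w[0].shape[0]
    y = np.zeros((cout, T, N))
    for k in range(params.n_subsets):
        graph = normalize_adjacency(params.a_bar[k])
        if params.b is not None:
            graph = graph + params.b[k]
        if params.w_theta is not None:
            graph = graph + data_driven_graph(
                x, params.w_theta[k], params.w_phi[k]
            )
        xg = np.einsum("ctn,nm->ctm", x, graph)
        y += np.tensordot(params.w[k], xg, axes=([1], [0]))
    if params.residual_w is not None:
        y += np.tensordot(params.residual_w, x, axes=([1], [0]))
    elif cin == cout:
        y += x
    else:
        raise ValueError("Cin != Cout requires a residual channel map")
    return y


def cow_skeleton_edges() -> list[tuple[str, str]]:
    """Undirected edges of the 8-keypoint back skeleton."""
    return [
        ("poll", "withers"),
        ("withers", "lumbar"),
        ("lumbar", "sacral_tuber"),
        ("withers", "left_scapula"),
        ("withers", "right_scapula"),
        ("sacral_tuber", "left_tuber_coxae"),
        ("sacral_tuber", "right_tuber_coxae"),
    ]


def cow_skeleton_subsets(center: str = "lumbar") -> list[np.ndarray]:
    """Root / centripetal / centrifugal adjacency triplet (Kv = 3).

    Follows the spatial-configuration partition convention: the root
    subset holds self-connections, the centripetal subset edges toward
    the skeleton centre (default the lumbar node, the spine's middle),
    and the centrifugal subset edges away from it.
    """
    names = list(KEYPOINT_NAMES)
    n = len(names)
    idx = {name: i for i, name in enumerate(names)}
    adj = np.zeros((n, n), dtype=int)
    for a, b in cow_skeleton_edges():
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    # BFS hop distance to the centre node
    dist = np.full(n, -1)
    dist[idx[center]] = 0
    frontier = [idx[center]]
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.nonzero(adj[i])[0]:
                if dist[j] < 0:
                    dist[j] = dist[i] + 1
                    nxt.append(j)
        frontier = nxt
    root = np.eye(n)
    centripetal = np.zeros((n, n))
    centrifugal = np.zeros((n, n))
    for i in range(n):
        for j in np.nonzero(adj[i])[0]:
            if dist[j] < dist[i]:
                centripetal[i, j] = 1
            elif dist[j] > dist[i]:
                centrifugal[i, j] = 1
    return [root, centripetal, centrifugal]


def selfcheck(seed: int = 0) -> dict[str, bool]:
    """Run the straight-line oracles of every forward op on random input."""
    rng = np.random.default_rng(seed)
    results: dict[str, bool] = {}

    n, C, d = 9, 6, 4
    tokens = WindowTokens(
        x=rng.normal(size=(n, C)),
        w_q=rng.normal(size=(C, d)),
        w_k=rng.normal(size=(C, d)),
        w_v=rng.normal(size=(C, d)),
        bias=rng.normal(size=(n, n)),
        fusion_logits=rng.normal(size=2),
    )
    out = assa_forward(tokens)
    results["assa_finite"] = bool(np.isfinite(out).all())
    scores = (tokens.x @ tokens.w_q) @ (tokens.x @ tokens.w_k).T / 2.0 + tokens.bias
    results["dsa_rows_sum_to_one"] = bool(
        np.allclose(softmax_rows(scores).sum(axis=1), 1.0, atol=EPS)
    )

    x = rng.normal(size=(5, 7, 4))
    params = FRFNParams(
        w1=rng.normal(size=(8, 4)),
        w2=rng.normal(size=(4, 4)),
        pconv=rng.normal(size=(1, 1, 3, 3)),
        dw=rng.normal(size=(4, 3, 3)),
    )
    results["frfn_shape"] = frfn_forward(x, params).shape == (5, 7, 4)

    path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
    a_norm = normalize_adjacency(path)
    results["path_normalisation"] = bool(
        np.isclose(a_norm[0, 1], 1 / np.sqrt(2))
    )

    xg = rng.normal(size=(3, 4, 8))
    ck = data_driven_graph(
        xg, rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
    )
    results["ck_rows_sum_to_one"] = bool(
        np.allclose(ck.sum(axis=1), 1.0, atol=EPS)
    )

    subsets = cow_skeleton_subsets()
    agc = AGCParams(
        w=[rng.normal(size=(3, 3)) for _ in range(3)],
        a_bar=subsets,
        b=[np.zeros((8, 8)) for _ in range(3)],
    )
    y = agc_forward(xg, agc)
    results["agc_shape"] = y.shape == xg.shape
    return results
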