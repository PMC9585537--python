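"""Patient-similarity graph, spectral filters, GCN layers and cut losses.

The graph is a symmetrized Gaussian-weighted kNN graph over samples; the
Laplacian is the combinatorial ``L = D - W`` (a symmetric-normalized
variant is available behind a flag).  Convolution is available on two
routes: exact spectral filtering through the eigenbasis, and the
polynomial filter computed by repeated sparse multiplication by ``L`` —
never through an eigendecomposition — which is K-hop localized.

Training is transductive node classification: a stack of polynomial
convolution layers with a dense readout, cross-entropy on labeled nodes
plus a differentiable min-cut auxiliary loss on a softmax cluster head.
Gradients are hand-derived (reverse-mode through the small fixed stack)
and checked against finite differences in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "Graph",
    "SpectralFilter",
    "ConvLayerParams",
    "AttentionParams",
    "GcnModel",
    "build_knn_graph",
    "graph_fourier",
    "graph_fourier_inverse",
    "spectral_convolve",
    "poly_filter",
    "gcn_layer",
    "attention_layer",
    "cut_value",
    "ncut_value",
    "mincut_loss",
    "mincut_loss_grad",
    "train_gcn",
    "gcn_forward",
]

logger = logging.getLogger(__name__)

# floor on soft cluster volumes so the normalized-cut term stays finite
_VOL_EPS = 1e-12


@dataclass
class Graph:
    """Weighted undirected graph with cached Laplacian spectrum."""

    W: np.ndarray
    normalized: bool = False
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if (W < 0).any():
            raise ValueError("W must be non-negative")
        np.fill_diagonal(W, 0.0)
        self.W = W

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        L = np.diag(self.degrees) - self.W
        if self.normalized:
            with np.errstate(divide="ignore"):
                dinv = np.where(self.degrees > 0, 1.0 / np.sqrt(self.degrees), 0.0)
            L = dinv[:, None] * L * dinv[None, :]
        return L

    @property
    def laplacian_sparse(self) -> sp.csr_matrix:
        return sp.csr_matrix(self.laplacian)

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, >= 0 up to roundoff) and orthonormal
        eigenvectors of the Laplacian; cached."""
        if self._eig is None:
            lam, chi = np.linalg.eigh(self.laplacian)
            self._eig = (lam, chi)
        return self._eig


@dataclass(frozen=True)
class SpectralFilter:
    """Polynomial filter coefficients theta_0..theta_K."""

    theta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.theta) < 1 or not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be a non-empty finite sequence")

    @property
    def order(self) -> int:
        return len(self.theta) - 1


def build_knn_graph(
    features: np.ndarray, k_nn: int, sigma: float | str = "auto"
) -> Graph:
    """Gaussian-weighted kNN graph over the rows of ``features``.

    ``w_ij = exp(-||x_i - x_j||^2 / sigma^2)`` when j is among i's k_nn
    nearest neighbors or vice versa (symmetrized by max); zero elsewhere
    and on the diagonal.  ``sigma="auto"`` uses the mean k_nn-th neighbor
    distance.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n = X.shape[0]
    if not 1 <= k_nn < n:
        raise ValueError(f"k_nn={k_nn} must satisfy 1 <= k_nn < n={n}")
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nn_order = np.argsort(d, axis=1, kind="stable")
    kth = d[np.arange(n), nn_order[:, k_nn - 1]]
    if sigma == "auto":
        sigma_val = float(kth.mean())
        if sigma_val <= 0:
            sigma_val = 1.0
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0:
            raise ValueError("sigma must be positive")
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_nn)
    mask[rows, nn_order[:, :k_nn].ravel()] = True
    mask |= mask.T
    np.fill_diagonal(d, 0.0)
    W = np.where(mask, np.exp(-(d**2) / sigma_val**2), 0.0)
    np.fill_diagonal(W, 0.0)
    return Graph(W=0.5 * (W + W.T))


def graph_fourier(g: Graph, f: np.ndarray) -> np.ndarray:
    """Expand a node signal in the Laplacian eigenbasis."""
    lam, chi = g.eigendecomposition()
    return chi.T @ np.asarray(f, dtype=float)


def graph_fourier_inverse(g: Graph, f_hat: np.ndarray) -> np.ndarray:
    """Inverse transform: synthesize a node signal from spectral coefficients."""
    lam, chi = g.eigendecomposition()
    return chi @ np.asarray(f_hat, dtype=float)


def spectral_convolve(g: Graph, f: np.ndarray, gains: np.ndarray) -> np.ndarray:
    """Exact spectral filtering: ``chi diag(gains) chi^T f``."""
    f = np.asarray(f, dtype=float)
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (g.n_nodes,):
        raise ValueError(f"gains must have length {g.n_nodes}")
    lam, chi = g.eigendecomposition()
    if f.ndim == 1:
        return chi @ (gains * (chi.T @ f))
    return chi @ (gains[:, None] * (chi.T @ f))


def poly_filter(g: Graph, filt: SpectralFilter, f: np.ndarray) -> np.ndarray:
    """Polynomial Laplacian filter ``sum_k theta_k L^k f``.

    Computed by repeated sparse matrix-vector products — no
    eigendecomposition — hence K-hop localized.
    """
    f = np.asarray(f, dtype=float)
    L = g.laplacian_sparse
    out = filt.theta[0] * f
    p = f
    for theta_k in filt.theta[1:]:
        p = L @ p
        out = out + theta_k * p
    return out


@dataclass
class ConvLayerParams:
    """One polynomial convolution layer: theta (K+1, F_in, F_out), bias (F_out,)."""

    theta: np.ndarray
    bias: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.theta.ndim != 3:
            raise ValueError("theta must have shape (K+1, F_in, F_out)")
        if self.bias.shape != (self.theta.shape[2],):
            raise ValueError("bias length must equal F_out")
        if self.activation not in ("relu", "tanh", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _activate(Z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(Z, 0.0)
    if kind == "tanh":
        return np.tanh(Z)
    return Z


def _laplacian_powers(g: Graph, H: np.ndarray, K: int) -> list[np.ndarray]:
    L = g.laplacian_sparse
    powers = [H]
    for _ in range(K):
        powers.append(L @ powers[-1])
    return powers


def gcn_layer(H: np.ndarray, g: Graph, params: ConvLayerParams) -> np.ndarray:
    """Polynomial graph convolution layer.

    Output channel j is ``sigma(sum_i sum_k theta[k, i, j] L^k H[:, i] + b_j)``.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    K = params.theta.shape[0] - 1
    if H.shape[1] != params.theta.shape[1]:
        raise ValueError(
            f"input has {H.shape[1]} channels, layer expects {params.theta.shape[1]}"
        )
    powers = _laplacian_powers(g, H, K)
    Z = params.bias[None, :].repeat(H.shape[0], axis=0)
    for k in range(K + 1):
        Z = Z + powers[k] @ params.theta[k]
    return _activate(Z, params.activation)


@dataclass
class AttentionParams:
    """Multi-head graph attention with edge gating.

    Per head k: Q[k], K[k], V[k] are (d_k, d) maps on node features and
    E[k] is (d_k, d_e) on edge features; O_h and O_e are (d, H*d_k)
    output maps for the concatenated heads.
    """

    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray
    E: np.ndarray
    O_h: np.ndarray
    O_e: np.ndarray

    @property
    def n_heads(self) -> int:
        return self.Q.shape[0]

    @property
    def d_head(self) -> int:
        return self.Q.shape[1]


def attention_layer(
    H: np.ndarray, E_feat: dict[tuple[int, int], np.ndarray], g: Graph,
    params: AttentionParams,
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray], dict[int, np.ndarray]]:
    """Edge-gated multi-head attention over graph neighborhoods.

    Per head, the pre-softmax score for edge (i, j) is
    ``sum((Q h_i) * (K h_j) * (E e_ij)) / sqrt(d_k)``; weights are
    softmax-normalized over each node's neighbors and aggregate ``V h_j``.
    Heads are concatenated through ``O_h`` (nodes) and ``O_e`` (edges).
    Returns (H', E', attention weights per node).  An isolated node falls
    back to a logged self-loop.
    """
    H = np.atleast_2d(np.asarray(H, dtype=float))
    n = g.n_nodes
    heads, d_k = params.n_heads, params.d_head
    sqrt_dk = np.sqrt(d_k)
    neighbors = [np.flatnonzero(g.W[i] > 0) for i in range(n)]

    Qh = np.einsum("kdf,nf->knd", params.Q, H)  # (H, n, d_k)
    Kh = np.einsum("kdf,nf->knd", params.K, H)
    Vh = np.einsum("kdf,nf->knd", params.V, H)

    H_heads = np.zeros((heads, n, d_k))
    weights: dict[int, np.ndarray] = {}
    new_edges: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        nbrs = neighbors[i]
        if nbrs.size == 0:
            logger.warning("node %d is isolated; using self-loop fallback", i)
            nbrs = np.array([i])
        scores = np.empty((heads, nbrs.size))
        gated = np.empty((heads, nbrs.size, d_k))
        for a, j in enumerate(nbrs):
            e_ij = E_feat.get((i, j), E_feat.get((j, i)))
            if e_ij is None:
                raise ValueError(f"edge ({i},{j}) has no edge feature")
            Ee = np.einsum("kde,e->kd", params.E, np.atleast_1d(e_ij))
            gated[:, a, :] = Qh[:, i, :] * Kh[:, j, :] * Ee / sqrt_dk
            scores[:, a] = gated[:, a, :].sum(axis=1)
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        weights[i] = w
        for k in range(heads):
            H_heads[k, i] = w[k] @ Vh[k, nbrs]
        for a, j in enumerate(nbrs):
            new_edges[(i, int(j))] = params.O_e @ gated[:, a, :].reshape(-1)

    concat = np.concatenate([H_heads[k] for k in range(heads)], axis=1)  # (n, H*d_k)
    H_out = concat @ params.O_h.T
    return H_out, new_edges, weights


def _partition_masks(partition: np.ndarray, n: int) -> list[np.ndarray]:
    partition = np.asarray(partition)
    if partition.shape != (n,):
        raise ValueError("partition must assign every node")
    if (partition < 0).any():
        raise ValueError("negative set index")
    return [partition == k for k in range(int(partition.max()) + 1)]


def cut_value(g: Graph, partition: np.ndarray) -> tuple[np.ndarray, float]:
    """Boundary weight per set and the half-sum total.

    ``cut(S_k, rest) = sum of W_ij over i in S_k, j outside``; the total is
    half the per-set sum so each crossing edge counts once.
    """
    masks = _partition_masks(partition, g.n_nodes)
    per_set = np.array([g.W[m][:, ~m].sum() for m in masks])
    return per_set, 0.5 * float(per_set.sum())


def ncut_value(g: Graph, partition: np.ndarray) -> float:
    """Normalized cut: sum over sets of boundary weight over set volume."""
    masks = _partition_masks(partition, g.n_nodes)
    deg = g.degrees
    total = 0.0
    for m in masks:
        vol = deg[m].sum()
        if vol <= 0:
            raise ValueError("partition contains a zero-volume set")
        total += g.W[m][:, ~m].sum() / vol
    return float(total)


def _check_soft_assignment(Y: np.ndarray, n: int) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != n:
        raise ValueError("Y must have one row per node")
    if (Y < -1e-12).any():
        raise ValueError("Y rows must be non-negative")
    if np.abs(Y.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("Y rows must sum to 1")
    return Y


def mincut_loss(Y: np.ndarray, g: Graph) -> float:
    """Differentiable min-cut relaxation on a soft assignment matrix.

    First term: the strict-lower-triangle sum of ``[(Y / Gamma)(1-Y)^T] * W``
    where column k of Gamma broadcasts the soft cluster volume
    ``sum_i d_i Y_ik`` — the soft analogue of the normalized cut.  Second
    term: squared deviation of each column sum from ``n / g_c`` (balance).
    """
    n = g.n_nodes
    Y = _check_soft_assignment(Y, n)
    g_c = Y.shape[1]
    vol = np.maximum(g.degrees @ Y, _VOL_EPS)  # (g_c,)
    A_low = np.tril(g.W, k=-1)
    term1 = 0.0
    for k in range(g_c):
        u = Y[:, k]
        term1 += (A_low @ (1.0 - u)) @ u / vol[k]
    balance = Y.sum(axis=0) - n / g_c
    return float(term1 + (balance**2).sum())


def mincut_loss_grad(Y: np.ndarray, g: Graph) -> np.ndarray:
    """Analytic gradient of :func:`mincut_loss` with respect to Y."""
    n = g.n_nodes
    Y = _check_soft_assignment(Y, n)
    g_c = Y.shape[1]
    deg = g.degrees
    vol = np.maximum(deg @ Y, _VOL_EPS)
    A_low = np.tril(g.W, k=-1)
    grad = np.empty_like(Y)
    for k in range(g_c):
        u = Y[:, k]
        s_k = (A_low @ (1.0 - u)) @ u
        ds_du = A_low @ (1.0 - u) - A_low.T @ u
        grad[:, k] = ds_du / vol[k] - s_k * deg / vol[k] ** 2
    grad += 2.0 * (Y.sum(axis=0) - n / g_c)[None, :]
    return grad


# ---------------------------------------------------------------------------
# Transductive training


@dataclass
class GcnModel:
    """Trained classifier state: conv layers, class readout, cluster head."""

    conv_layers: list[ConvLayerParams]
    W_cls: np.ndarray
    b_cls: np.ndarray
    W_clu: np.ndarray
    b_clu: np.ndarray
    K: int
    lambda_cut: float
    g_c: int
    seed: int
    l_scale: float = 1.0  # Laplacian divisor used during training
    history: list[dict] = field(default_factory=list)


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(model: GcnModel, g: Graph, X: np.ndarray) -> dict[str, np.ndarray]:
    """Forward pass; returns hidden states, class probabilities and the
    cluster-head soft assignment."""
    H = np.atleast_2d(np.asarray(X, dtype=float))
    L = g.laplacian_sparse / model.l_scale
    hidden = [H]
    for layer in model.conv_layers:
        K = layer.theta.shape[0] - 1
        powers = [H]
        for _ in range(K):
            powers.append(L @ powers[-1])
        Z = layer.bias[None, :] + sum(powers[k] @ layer.theta[k] for k in range(K + 1))
        H = _activate(Z, layer.activation)
        hidden.append(H)
    logits_cls = H @ model.W_cls + model.b_cls
    logits_clu = H @ model.W_clu + model.b_clu
    return {
        "hidden": hidden,
        "probs": _softmax(logits_cls),
        "Y_clu": _softmax(logits_clu),
    }


def _init_model(
    F_in: int, hidden: tuple[int, ...], n_classes: int, K: int, g_c: int,
    lambda_cut: float, seed: int,
) -> GcnModel:
    rng = np.random.default_rng(seed)
    layers = []
    f_prev = F_in
    for f_out in hidden:
        scale = np.sqrt(2.0 / (f_prev * (K + 1)))
        theta = rng.normal(0.0, scale, size=(K + 1, f_prev, f_out))
        layers.append(ConvLayerParams(theta=theta, bias=np.zeros(f_out)))
        f_prev = f_out
    W_cls = rng.normal(0.0, np.sqrt(2.0 / f_prev), size=(f_prev, n_classes))
    W_clu = rng.normal(0.0, np.sqrt(2.0 / f_prev), size=(f_prev, g_c))
    return GcnModel(
        conv_layers=layers,
        W_cls=W_cls,
        b_cls=np.zeros(n_classes),
        W_clu=W_clu,
        b_clu=np.zeros(g_c),
        K=K,
        lambda_cut=lambda_cut,
        g_c=g_c,
        seed=seed,
    )


def train_gcn(
    g: Graph,
    X: np.ndarray,
    y: np.ndarray,
    train_mask: np.ndarray,
    hidden: tuple[int, ...] = (16, 16),
    K: int = 3,
    lambda_cut: float = 0.1,
    g_c: int = 2,
    epochs: int = 500,
    lr: float = 0.05,
    momentum: float = 0.9,
    seed: int = 0,
    checkpoints: tuple[int, ...] = (100, 200, 300, 400, 500),
    eval_fn=None,
    rescale: bool = True,
) -> GcnModel:
    """Train the transductive classifier by momentum gradient descent.

    Loss = cross-entropy over labeled (train-mask) nodes
    + ``(lambda_cut / n)`` * :func:`mincut_loss` on the cluster head.  The
    1/n factor puts the auxiliary term (whose balance part grows like n^2)
    on the same footing as the mean cross-entropy; without it the cut
    gradients drown the classification signal.  All randomness flows from
    ``seed``.  ``eval_fn(epoch, probs)`` is invoked at each checkpoint
    epoch and its result appended to ``model.history``.

    ``rescale`` divides the Laplacian by its largest eigenvalue before
    training.  This only reparameterizes the polynomial coefficients
    (theta_k absorb lambda_max^k) — the model class is unchanged — but it
    keeps repeated applications of L numerically bounded.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    train_mask = np.asarray(train_mask, dtype=bool)
    n, F_in = X.shape
    classes = np.unique(y[train_mask])
    n_classes = int(classes.max()) + 1
    model = _init_model(F_in, hidden, n_classes, K, g_c, lambda_cut, seed)

    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    n_labeled = int(train_mask.sum())
    L = g.laplacian_sparse
    if rescale:
        v0 = np.ones(n) / np.sqrt(n)  # fixed start vector: deterministic runs
        lam_max = float(
            sp.linalg.eigsh(L, k=1, which="LA", v0=v0, return_eigenvectors=False)[0]
        )
        if lam_max > 0:
            L = L / lam_max
            model.l_scale = lam_max

    params = []
    for layer in model.conv_layers:
        params.extend([layer.theta, layer.bias])
    params.extend([model.W_cls, model.b_cls, model.W_clu, model.b_clu])
    velocity = [np.zeros_like(p) for p in params]

    for epoch in range(1, epochs + 1):
        # forward with caches
        hidden_states = [X]
        caches = []
        H = X
        for layer in model.conv_layers:
            powers = [H]
            for _ in range(K):
                powers.append(L @ powers[-1])
            Z = layer.bias[None, :] + sum(
                powers[k] @ layer.theta[k] for k in range(K + 1)
            )
            H = _activate(Z, layer.activation)
            caches.append((powers, Z))
            hidden_states.append(H)
        logits_cls = H @ model.W_cls + model.b_cls
        logits_clu = H @ model.W_clu + model.b_clu
        P = _softmax(logits_cls)
        Y_clu = _softmax(logits_clu)

        # backward
        dZ_cls = np.zeros_like(P)
        dZ_cls[train_mask] = (P[train_mask] - onehot[train_mask]) / n_labeled
        G_Y = (lambda_cut / n) * mincut_loss_grad(Y_clu, g)
        dZ_clu = Y_clu * (G_Y - (G_Y * Y_clu).sum(axis=1, keepdims=True))

        grads: list[np.ndarray] = []
        dH = dZ_cls @ model.W_cls.T + dZ_clu @ model.W_clu.T
        head_grads = [
            H.T @ dZ_cls, dZ_cls.sum(axis=0), H.T @ dZ_clu, dZ_clu.sum(axis=0),
        ]
        for layer, (powers, Z) in zip(
            reversed(model.conv_layers), reversed(caches)
        ):
            if layer.activation == "relu":
                dZ = dH * (Z > 0)
            elif layer.activation == "tanh":
                dZ = dH * (1.0 - np.tanh(Z) ** 2)
            else:
                dZ = dH
            dtheta = np.stack([powers[k].T @ dZ for k in range(K + 1)])
            dbias = dZ.sum(axis=0)
            dH_in = dZ @ layer.theta[0].T
            back = dZ
            for k in range(1, K + 1):
                back = L @ back  # L symmetric: (L^k)^T = L^k
                dH_in = dH_in + back @ layer.theta[k].T
            grads.insert(0, dbias)
            grads.insert(0, dtheta)
            dH = dH_in
        grads.extend(head_grads)

        for p, v, gd in zip(params, velocity, grads):
            v *= momentum
            v -= lr * gd
            p += v

        if epoch in checkpoints and eval_fn is not None:
            out = gcn_forward(model, g, X)
            model.history.append(eval_fn(epoch, out["probs"]))
    return model
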