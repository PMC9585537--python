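"""Linear and kernel discriminant feature extraction and classification.

Two equivalent routes to a between-class-whitened feature space:

* direct: eigendecompose the between-class scatter ``S_b`` and whiten
  (:func:`scatter_matrices`, :func:`discriminative_basis`);
* kernel: assemble the class-side counterpart of ``S_b`` from Gram-matrix
  blocks (:func:`gram_matrix`, :func:`kernel_between_class_basis`) so the
  feature map is never formed explicitly.

On top of the projected features, per-class covariances are shrunk by a
pair of regularization parameters ``(alpha, gamma)`` — ``alpha`` toward the
pooled covariance, ``gamma`` toward a scaled identity — and classification
uses the Mahalanobis/Bayes rule (squared covariance-weighted distance plus
log-determinant minus twice log-prior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelSpec",
    "KdaModel",
    "scatter_matrices",
    "discriminative_basis",
    "gram_matrix",
    "kernel_between_class_basis",
    "project",
    "regularized_covariance",
    "mahalanobis_classify",
    "fit_kda",
    "pooled_trace_preset",
]

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class KernelSpec:
    """Kernel selector: ``linear``, ``rbf`` (bandwidth sigma) or
    ``polynomial`` (degree d, i.e. (x.z + 1)^d)."""

    kind: str = "rbf"
    sigma: float | None = None  # None => median pairwise distance at fit time
    degree: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf", "polynomial"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "rbf" and self.sigma is not None and not self.sigma > 0:
            raise ValueError("rbf sigma must be positive")
        if self.kind == "polynomial":
            if int(self.degree) != self.degree or self.degree < 1:
                raise ValueError("polynomial degree must be an integer >= 1")


@dataclass
class KdaModel:
    """Fitted kernel discriminant model.

    Projection: ``y = lam^{-1} E^T D_s (m(z) - g(z) 1)`` where ``m`` holds
    per-class mean kernel evaluations against the training set, ``g`` the
    global mean, ``D_s = diag(sqrt(C_i/N))``, and ``(E, lam)`` the top-M
    eigenpairs of the class-side between-class matrix.
    """

    kernel: KernelSpec
    X_train: np.ndarray
    classes: np.ndarray
    class_counts: np.ndarray
    priors: np.ndarray
    M: int
    E: np.ndarray  # (C, M) eigenvectors, class side
    lam: np.ndarray  # (M,) positive eigenvalues
    class_means: np.ndarray  # (C, M) projected training class means
    covariances: np.ndarray  # (C, M, M) regularized
    alpha: float
    gamma: float
    y_train: np.ndarray | None = None


def scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-class and within-class scatter.

    ``S_b = sum_i C_i (mu_i - mu)(mu_i - mu)^T / N`` and
    ``S_w = sum_i sum_j (x_ij - mu_i)(x_ij - mu_i)^T`` (unnormalized), so
    that ``N * S_b + S_w`` equals the total scatter about the global mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, j = X.shape
    mu = X.mean(axis=0)
    S_b = np.zeros((j, j))
    S_w = np.zeros((j, j))
    for cls in classes:
        Xc = X[y == cls]
        mu_c = Xc.mean(axis=0)
        d = mu_c - mu
        S_b += Xc.shape[0] * np.outer(d, d)
        R = Xc - mu_c
        S_w += R.T @ R
    S_b /= n
    S_b = 0.5 * (S_b + S_b.T)
    S_w = 0.5 * (S_w + S_w.T)
    return S_b, S_w


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def discriminative_basis(S_b: np.ndarray, M: int) -> np.ndarray:
    """Whitening basis U with ``U^T S_b U = I_M``.

    Columns are the top-M eigenvectors of ``S_b`` (descending eigenvalue),
    scaled by ``lambda^{-1/2}``.  Rejects if fewer than M eigenvalues exceed
    the rank tolerance.
    """
    S_b = np.asarray(S_b, dtype=float)
    w, V = eigh(S_b)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    rank = int(np.sum(w > _EIG_TOL))
    if rank < M:
        raise ValueError(f"between-class scatter has rank {rank} < M={M}")
    V = _fix_signs(V[:, :M])
    return V / np.sqrt(w[:M])


def _kernel_eval(A: np.ndarray, B: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "rbf":
        if spec.sigma is None:
            raise ValueError("rbf sigma unresolved; fit the model first")
        d2 = cdist(A, B, "sqeuclidean")
        return np.exp(-d2 / (2.0 * spec.sigma**2))
    return (A @ B.T + 1.0) ** int(spec.degree)


def gram_matrix(X: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """N x N matrix of pairwise kernel evaluations; symmetrized exactly."""
    X = np.asarray(X, dtype=float)
    K = _kernel_eval(X, X, kernel)
    return 0.5 * (K + K.T)


def _class_weight_matrix(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """N x C matrix with entry 1/C_c on (i, c) when sample i is in class c."""
    n = y.shape[0]
    P = np.zeros((n, classes.size))
    for c, cls in enumerate(classes):
        idx = y == cls
        P[idx, c] = 1.0 / idx.sum()
    return P


def kernel_between_class_basis(
    K: np.ndarray, y: np.ndarray, M: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-M eigenpairs of the class-side between-class matrix.

    The N-side between-class operator has the same nonzero spectrum as the
    C x C matrix ``D_s G D_s`` where ``G_lh`` is the centered class-mean
    Gram ``(mean_l - mean)(mean_h - mean)`` assembled from K blocks and
    ``D_s = diag(sqrt(C_i/N))``.  Rejects if fewer than M eigenvalues are
    positive.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y)
    n = K.shape[0]
    if K.shape != (n, n) or y.shape != (n,):
        raise ValueError("K must be square and aligned with y")
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    P = _class_weight_matrix(y, classes)
    Mcc = P.T @ K @ P  # class-mean inner products
    mvec = (P.T @ K).mean(axis=1)  # class mean . global mean
    s = K.mean()  # global mean . global mean
    G = Mcc - mvec[:, None] - mvec[None, :] + s
    d_s = np.sqrt(counts / n)
    A = d_s[:, None] * G * d_s[None, :]
    A = 0.5 * (A + A.T)
    w, V = eigh(A)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    n_pos = int(np.sum(w > _EIG_TOL))
    if n_pos < M:
        raise ValueError(f"only {n_pos} positive eigenvalues, need M={M}")
    return _fix_signs(V[:, :M]), w[:M]


def project(samples: np.ndarray, model: KdaModel) -> np.ndarray:
    """Map samples into the M-dimensional whitened discriminant space."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if model.E.size == 0:
        raise ValueError("model is not fitted")
    Kx = _kernel_eval(model.X_train, samples, model.kernel)  # (N, m)
    P = _class_weight_matrix(model.y_train, model.classes)
    mcl = P.T @ Kx  # (C, m) per-class mean kernel rows
    g = Kx.mean(axis=0)  # (m,) global mean
    d_s = np.sqrt(model.class_counts / model.class_counts.sum())
    centered = d_s[:, None] * (mcl - g[None, :])
    return (model.E.T @ centered / model.lam[:, None]).T  # (m, M)


def regularized_covariance(
    Y_proj: np.ndarray, y: np.ndarray, alpha: float, gamma: float
) -> np.ndarray:
    """Per-class (alpha, gamma)-regularized covariances in projected space.

    ``Sigma_i(alpha) = [(1-alpha) S_i + alpha S] / C_i(alpha)`` with
    ``C_i(alpha) = (1-alpha) C_i + alpha N``, per-class unnormalized scatter
    ``S_i`` and pooled ``S = sum_i S_i``; then shrunk toward the scaled
    identity: ``(1-gamma) Sigma_i(alpha) + (gamma/M) tr[Sigma_i(alpha)] I``.

    alpha=1 gives every class the pooled matrix ``S/N``; gamma=1 gives a
    scalar multiple of the identity.  Returns an array of shape (C, M, M).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    Y_proj = np.atleast_2d(np.asarray(Y_proj, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)
    n, m_dim = Y_proj.shape
    S_i = np.zeros((classes.size, m_dim, m_dim))
    counts = np.zeros(classes.size)
    for c, cls in enumerate(classes):
        Yc = Y_proj[y == cls]
        counts[c] = Yc.shape[0]
        R = Yc - Yc.mean(axis=0)
        S_i[c] = R.T @ R
    S_pooled = S_i.sum(axis=0)
    out = np.empty_like(S_i)
    eye = np.eye(m_dim)
    for c in range(classes.size):
        c_alpha = (1.0 - alpha) * counts[c] + alpha * n
        sig_a = ((1.0 - alpha) * S_i[c] + alpha * S_pooled) / c_alpha
        sig = (1.0 - gamma) * sig_a + (gamma / m_dim) * np.trace(sig_a) * eye
        out[c] = 0.5 * (sig + sig.T)
    return out


def mahalanobis_classify(
    Q: np.ndarray, model: KdaModel
) -> tuple[np.ndarray, np.ndarray]:
    """Classify projected queries by the Mahalanobis/Bayes rule.

    ``d_i(q) = (q - mean_i)^T Sigma_i^{-1} (q - mean_i) + ln|Sigma_i|
    - 2 ln pi_i``; the predicted class minimizes ``d_i`` (ties to the lowest
    class index).  Returns (labels, scores) with scores of shape (m, C).
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    n_classes = model.classes.size
    d = np.empty((Q.shape[0], n_classes))
    for c in range(n_classes):
        try:
            factor = cho_factor(model.covariances[c], lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular covariance for class index {c}") from exc
        diff = Q - model.class_means[c]
        sol = cho_solve(factor, diff.T).T
        quad = np.einsum("ij,ij->i", diff, sol)
        logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
        d[:, c] = quad + logdet - 2.0 * np.log(model.priors[c])
    labels = model.classes[np.argmin(d, axis=1)]
    return labels, d


def pooled_trace_preset(Y_proj: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Named preset: alpha=1 with gamma = (tr(S/N) + M)/M, clamped to 1.

    The unclamped value exceeds 1 whenever the pooled covariance has
    positive trace, so the clamp is logged.
    """
    Y_proj = np.atleast_2d(np.asarray(Y_proj, dtype=float))
    n, m_dim = Y_proj.shape
    S = np.zeros((m_dim, m_dim))
    for cls in np.unique(y):
        Yc = Y_proj[np.asarray(y) == cls]
        R = Yc - Yc.mean(axis=0)
        S += R.T @ R
    gamma = (np.trace(S / n) + m_dim) / m_dim
    if gamma > 1.0:
        logger.warning("preset gamma %.4f exceeds 1; clamping", gamma)
        gamma = 1.0
    return 1.0, float(gamma)


def fit_kda(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec | None = None,
    alpha: float = 0.5,
    gamma: float = 0.1,
    M: int | None = None,
) -> KdaModel:
    """Fit the kernel discriminant model end to end.

    Resolves the rbf bandwidth to the median pairwise training distance when
    unspecified, computes the class-side basis, projects the training set,
    stores per-class means, regularized covariances and priors.
    ``M`` defaults to min(C-1, number of positive eigenvalues).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if kernel is None:
        kernel = KernelSpec(kind="rbf")
    if kernel.kind == "rbf" and kernel.sigma is None:
        med = float(np.median(pdist(X)))
        kernel = KernelSpec(kind="rbf", sigma=med if med > 0 else 1.0)
    classes = np.unique(y)
    counts = np.array([(y == c).sum() for c in classes])
    K = gram_matrix(X, kernel)
    max_m = classes.size - 1
    if M is None:
        # largest attainable rank up to C-1
        M = max_m
        while M > 1:
            try:
                kernel_between_class_basis(K, y, M)
                break
            except ValueError:
                M -= 1
    E, lam = kernel_between_class_basis(K, y, M)

    model = KdaModel(
        kernel=kernel,
        X_train=X,
        classes=classes,
        class_counts=counts,
        priors=counts / counts.sum(),
        M=M,
        E=E,
        lam=lam,
        class_means=np.zeros((classes.size, M)),
        covariances=np.zeros((classes.size, M, M)),
        alpha=alpha,
        gamma=gamma,
        y_train=y,
    )
    Y_proj = project(X, model)
    for c, cls in enumerate(classes):
        model.class_means[c] = Y_proj[y == cls].mean(axis=0)
    model.covariances = regularized_covariance(Y_proj, y, alpha, gamma)
    return model
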