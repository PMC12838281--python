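"""Partial-least-squares dimension reduction with LDA / kernel-SVM heads,
and a multiple-kernel ("deep kernel learning") SVM.

The PLS core is the classical NIPALS algorithm with orthogonal scores: at
component h the loading weight w_h ∝ X'y is normalized to unit length, the
score is s_h = X w_h, the X- and y-loadings are obtained by regressing X
and y on s_h, and X and y are deflated before the next component.  The
regression coefficients assemble as beta = W (K'W)^{-1} v.  For a
multi-class response the label is one-hot encoded and the two-block
(PLS2) inner iteration is used.

Classification heads on the PLS scores:

* LDA with shared covariance (the Gaussian discriminant
  delta_c(s) = -log|Sigma|/2 - (s-mu_c)' Sigma^{-1} (s-mu_c)/2 + log pi_c);
* soft-margin SVMs under a registry of kernels — polynomial, Bessel,
  Laplacian, linear, spline — one-vs-rest for 3 classes.

The multiple-kernel SVM combines base kernels as K = sum_n l_n K_n with
simplex weights (l_n >= 0, sum l_n = 1), alternating between solving the
SVM dual at fixed weights and reweighting each kernel by its contribution
to the discriminant norm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import jv
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

__all__ = [
    "PLSModel",
    "KernelSpec",
    "KernelSVM",
    "PLSLDAModel",
    "PLSSVMModel",
    "DKLSVMModel",
    "pls_fit",
    "pls_transform",
    "pls_predict",
    "pls_lda_fit",
    "pls_lda_predict",
    "kernel_eval",
    "gram_matrix",
    "pls_svm_fit",
    "pls_svm_predict",
    "dkl_svm_fit",
    "dkl_svm_predict",
]


# ---------------------------------------------------------------------------
# NIPALS PLS


@dataclass
class PLSModel:
    """A fitted NIPALS PLS decomposition.

    W are unit-norm loading weights, S orthogonal scores, K the X-loadings
    and v the y-loadings; beta = W (K'W)^{-1} v maps centered X to centered
    predictions.
    """

    W: np.ndarray          # (J, H) loading weights, unit columns
    S: np.ndarray          # (n, H) orthogonal scores
    K: np.ndarray          # (J, H) X-loadings
    v: np.ndarray          # (H, m) y-loadings
    beta: np.ndarray       # (J, m) regression coefficients
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_components: int
    rotation: np.ndarray = field(init=False)  # R = W (K'W)^{-1}

    def __post_init__(self) -> None:
        self.rotation = self.W @ np.linalg.inv(self.K.T @ self.W)


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int = 10) -> PLSModel:
    """Fit NIPALS PLS on centered data.

    A 1-D response uses the direct PLS1 recursion (w_h = X'y normalized);
    a 2-D response (e.g. one-hot classes) uses the PLS2 inner iteration.
    Components past the effective rank are truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(y, dtype=float)
    univariate = Y.ndim == 1
    if univariate:
        Y = Y[:, None]
    if X.std(axis=0).max() == 0:
        raise ValueError("X has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xh = X - x_mean
    Yh = Y - y_mean
    n, J = Xh.shape
    m = Yh.shape[1]
    H = n_components

    Ws, Ss, Ks, vs = [], [], [], []
    x_scale = np.linalg.norm(Xh) + 1e-300
    for h in range(H):
        if univariate or m == 1:
            w = Xh.T @ Yh[:, 0]
        else:
            # PLS2 inner NIPALS loop
            u = Yh[:, int(np.argmax(Yh.var(axis=0)))].copy()
            w = Xh.T @ u
            for _ in range(500):
                nw = np.linalg.norm(w)
                if nw == 0:
                    break
                w_unit = w / nw
                s = Xh @ w_unit
                c = Yh.T @ s / (s @ s)
                u_new = Yh @ c / (c @ c) if (c @ c) > 0 else u
                if np.linalg.norm(u_new - u) <= 1e-12 * (np.linalg.norm(u) + 1e-300):
                    u = u_new
                    break
                u = u_new
                w = Xh.T @ u
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * x_scale:
            warnings.warn(
                f"rank exhausted after {h} components (requested {H}); truncating",
                stacklevel=2,
            )
            break
        w = w / nw
        s = Xh @ w
        ss = s @ s
        if ss <= (1e-12 * x_scale) ** 2:
            warnings.warn(
                f"rank exhausted after {h} components (requested {H}); truncating",
                stacklevel=2,
            )
            break
        k = Xh.T @ s / ss
        vh = Yh.T @ s / ss
        Xh = Xh - np.outer(s, k)
        Yh = Yh - np.outer(s, vh)
        Ws.append(w)
        Ss.append(s)
        Ks.append(k)
        vs.append(vh)

    if not Ws:
        raise ValueError("no PLS components could be extracted")
    W = np.column_stack(Ws)
    S = np.column_stack(Ss)
    K = np.column_stack(Ks)
    v = np.vstack(vs)
    beta = W @ np.linalg.inv(K.T @ W) @ v
    model = PLSModel(
        W=W, S=S, K=K, v=v, beta=beta,
        x_mean=x_mean, y_mean=y_mean, n_components=W.shape[1],
    )
    return model


def pls_transform(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Scores of new data; reproduces the stored training scores exactly."""
    X = np.asarray(X, dtype=float)
    return (X - model.x_mean) @ model.rotation


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    pred = model.y_mean + (X - model.x_mean) @ model.beta
    return pred


# ---------------------------------------------------------------------------
# PLS-LDA


def _fit_standardizer(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


@dataclass
class PLSLDAModel:
    pls: PLSModel
    classes_: np.ndarray
    means: np.ndarray       # (C, H) class means in score space
    cov_inv: np.ndarray
    log_det: float
    log_priors: np.ndarray
    x_mu: np.ndarray | None = None
    x_sd: np.ndarray | None = None


def pls_lda_fit(
    X: np.ndarray, y: np.ndarray, n_components: int = 10, ridge: float = 1e-8
) -> PLSLDAModel:
    """PLS scores followed by LDA with a shared (pooled) covariance.

    Features are z-scored (training statistics) before PLS so heterogenous
    feature scales do not dominate the covariance direction.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(X, dtype=float)
    x_mu, x_sd = _fit_standardizer(X)
    X = (X - x_mu) / x_sd
    onehot = (y[:, None] == classes[None, :]).astype(float)
    pls = pls_fit(X, onehot, n_components)
    S = pls.S
    H = S.shape[1]
    means = np.vstack([S[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((H, H))
    for ci, c in enumerate(classes):
        d = S[y == c] - means[ci]
        pooled += d.T @ d
    pooled /= max(len(y) - len(classes), 1)
    pooled += ridge * np.eye(H)
    try:
        cov_inv = np.linalg.inv(pooled)
        sign, log_det = np.linalg.slogdet(pooled)
        if sign <= 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled score covariance is singular") from exc
    priors = np.array([(y == c).mean() for c in classes])
    return PLSLDAModel(
        pls=pls, classes_=classes, means=means,
        cov_inv=cov_inv, log_det=log_det, log_priors=np.log(priors),
        x_mu=x_mu, x_sd=x_sd,
    )


def pls_lda_predict(
    model: PLSLDAModel, X: np.ndarray, return_posterior: bool = False
):
    """Argmax of the Gaussian discriminant over classes; posteriors via
    softmax of the discriminant values."""
    X = np.asarray(X, dtype=float)
    if model.x_mu is not None:
        X = (X - model.x_mu) / model.x_sd
    S = pls_transform(model.pls, X)
    delta = np.empty((S.shape[0], len(model.classes_)))
    for ci in range(len(model.classes_)):
        d = S - model.means[ci]
        maha = np.einsum("ij,jk,ik->i", d, model.cov_inv, d)
        delta[:, ci] = -0.5 * model.log_det - 0.5 * maha + model.log_priors[ci]
    labels = model.classes_[np.argmax(delta, axis=1)]
    if return_posterior:
        z = delta - delta.max(axis=1, keepdims=True)
        post = np.exp(z)
        post /= post.sum(axis=1, keepdims=True)
        return labels, post
    return labels


# ---------------------------------------------------------------------------
# Kernel registry


@dataclass(frozen=True)
class KernelSpec:
    """A named kernel with its parameters.

    polynomial: (s_i . s_j + 1)^degree; laplacian: exp(-||s_i-s_j||/sigma);
    linear: s_i . s_j; spline: the cubic-spline kernel applied
    coordinate-wise and multiplied; bessel: the first-kind Bessel kernel
    J_{order+1}(sigma r) / (sigma r)^{order+1}, normalized so k(0) = 1 (the
    analytic limit at r -> 0).
    """

    name: str
    degree: int = 2
    sigma: float = 1.0
    order: int = 0

    def __post_init__(self) -> None:
        if self.name not in ("polynomial", "bessel", "laplacian", "linear", "spline"):
            raise ValueError(f"unknown kernel: {self.name!r}")
        if self.name in ("bessel", "laplacian") and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.name == "polynomial" and (self.degree < 1 or int(self.degree) != self.degree):
            raise ValueError("degree must be a positive integer")


def _bessel_kernel(r: np.ndarray, sigma: float, order: int) -> np.ndarray:
    nu = order + 1
    z = sigma * np.asarray(r, dtype=float)
    # J_nu(z)/z^nu -> 1/(2^nu Gamma(nu+1)) as z -> 0; normalize so k(0)=1
    norm = 2.0**nu * gamma_fn(nu + 1)
    out = np.empty_like(z)
    small = z < 1e-8
    out[small] = 1.0
    zs = z[~small]
    out[~small] = norm * jv(nu, zs) / zs**nu
    return out


def _spline_1d(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    m = np.minimum(x, y)
    return 1.0 + x * y + x * y * m - (x + y) / 2.0 * m**2 + m**3 / 3.0


def gram_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray | None = None) -> np.ndarray:
    """Kernel matrix k(A_i, B_j); symmetric when B is A."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("vectors must share dimensionality")
    if spec.name == "linear":
        return A @ B.T
    if spec.name == "polynomial":
        return (A @ B.T + 1.0) ** spec.degree
    if spec.name in ("laplacian", "bessel"):
        d2 = (
            (A**2).sum(axis=1)[:, None]
            + (B**2).sum(axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        r = np.sqrt(np.maximum(d2, 0.0))
        if spec.name == "laplacian":
            return np.exp(-r / spec.sigma)
        return _bessel_kernel(r, spec.sigma, spec.order)
    if spec.name == "spline":
        G = np.ones((A.shape[0], B.shape[0]))
        for j in range(A.shape[1]):
            G *= _spline_1d(A[:, j][:, None], B[:, j][None, :])
        return G
    raise ValueError(spec.name)


def kernel_eval(spec: KernelSpec, si: np.ndarray, sj: np.ndarray) -> float:
    """Kernel value for a single pair of vectors."""
    si = np.asarray(si, dtype=float).ravel()
    sj = np.asarray(sj, dtype=float).ravel()
    if si.shape != sj.shape:
        raise ValueError("vectors must share dimensionality")
    return float(gram_matrix(spec, si[None, :], sj[None, :])[0, 0])


def _clip_psd(G: np.ndarray, warn_label: str) -> np.ndarray:
    """Eigenvalue-clip a symmetric Gram matrix to PSD if needed."""
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -1e-8 * max(abs(vals.max()), 1.0):
        warnings.warn(
            f"{warn_label} Gram matrix is not PSD "
            f"(min eigenvalue {vals.min():.3g}); clipping at 0",
            stacklevel=3,
        )
        vals = np.clip(vals, 0.0, None)
        G = (vecs * vals) @ vecs.T
    return G


# ---------------------------------------------------------------------------
# Kernel SVM on precomputed Grams (one-vs-rest)


class KernelSVM:
    """Soft-margin SVM over a precomputed kernel, one-vs-rest multi-class."""

    def __init__(self, C: float = 1.0):
        self.C = C
        self.clf = OneVsRestClassifier(SVC(kernel="precomputed", C=C))

    def fit(self, G_train: np.ndarray, y: np.ndarray) -> "KernelSVM":
        self.clf.fit(G_train, y)
        self.classes_ = self.clf.classes_
        return self

    def predict(self, G_test_train: np.ndarray) -> np.ndarray:
        return self.clf.predict(G_test_train)

    def decision_function(self, G_test_train: np.ndarray) -> np.ndarray:
        return self.clf.decision_function(G_test_train)


@dataclass
class PLSSVMModel:
    pls: PLSModel
    svm: KernelSVM
    spec: KernelSpec
    train_scores: np.ndarray
    classes_: np.ndarray
    scale_shift: np.ndarray | None = None
    scale_div: np.ndarray | None = None
    x_mu: np.ndarray | None = None
    x_sd: np.ndarray | None = None


def _scale_scores(spec: KernelSpec, S: np.ndarray):
    """Kernel-appropriate score scaling fitted on the training scores.

    Inner-product and distance kernels get z-scored scores so one dominant
    component cannot swamp the kernel (and so libsvm converges on
    well-conditioned Grams); the spline kernel gets min-max scaling to
    [0, 1], its usual domain.
    """
    if spec.name == "spline":
        shift = S.min(axis=0)
        div = np.ptp(S, axis=0)
        div[div == 0] = 1.0
    else:
        shift = S.mean(axis=0)
        div = S.std(axis=0)
        div[div == 0] = 1.0
    return shift, div


def pls_svm_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 10,
    spec: KernelSpec | None = None,
    C: float = 1.0,
) -> PLSSVMModel:
    """Kernel SVM (one-vs-rest) trained on PLS scores.

    Non-PSD Grams (possible for the Bessel and spline kernels) are
    eigenvalue-clipped with a warning before training.
    """
    y = np.asarray(y)
    spec = spec or KernelSpec("polynomial", degree=2)
    classes = np.unique(y)
    X = np.asarray(X, dtype=float)
    x_mu, x_sd = _fit_standardizer(X)
    X = (X - x_mu) / x_sd
    onehot = (y[:, None] == classes[None, :]).astype(float)
    pls = pls_fit(X, onehot if len(classes) > 2 else (y == classes[-1]).astype(float),
                  n_components)
    S = pls.S
    shift, div = _scale_scores(spec, S)
    if shift is not None:
        S = (S - shift) / div
    G = gram_matrix(spec, S)
    if spec.name in ("bessel", "spline"):
        G = _clip_psd(G, spec.name)
    svm = KernelSVM(C=C).fit(G, y)
    return PLSSVMModel(
        pls=pls, svm=svm, spec=spec, train_scores=S, classes_=classes,
        scale_shift=shift, scale_div=div, x_mu=x_mu, x_sd=x_sd,
    )


def _new_scores(model: PLSSVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if model.x_mu is not None:
        X = (X - model.x_mu) / model.x_sd
    S_new = pls_transform(model.pls, X)
    if model.scale_shift is not None:
        S_new = (S_new - model.scale_shift) / model.scale_div
    return S_new


def pls_svm_predict(model: PLSSVMModel, X: np.ndarray) -> np.ndarray:
    G = gram_matrix(model.spec, _new_scores(model, X), model.train_scores)
    return model.svm.predict(G)


def pls_svm_predict_proba(model: PLSSVMModel, X: np.ndarray) -> np.ndarray:
    """Probability-like scores: softmax over one-vs-rest decision values."""
    G = gram_matrix(model.spec, _new_scores(model, X), model.train_scores)
    dec = model.svm.decision_function(G)
    if dec.ndim == 1:
        dec = np.column_stack([-dec, dec])
    z = dec - dec.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Multiple-kernel SVM


@dataclass
class DKLSVMModel:
    svm: KernelSVM
    kernel_list: list[KernelSpec]
    weights: np.ndarray
    X_train: np.ndarray
    classes_: np.ndarray
    n_iter: int


def _kernel_contributions(svm: KernelSVM, grams: list[np.ndarray]) -> np.ndarray:
    """Per-kernel contribution to the discriminant norm: sum over the
    one-vs-rest heads of alpha' K_n alpha on the support set."""
    contrib = np.zeros(len(grams))
    for est in svm.clf.estimators_:
        sv = est.support_
        alpha = est.dual_coef_[0]
        for n, G in enumerate(grams):
            contrib[n] += float(alpha @ G[np.ix_(sv, sv)] @ alpha)
    return np.maximum(contrib, 0.0)


def dkl_svm_fit(
    X: np.ndarray,
    y: np.ndarray,
    kernel_list: list[KernelSpec],
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 30,
) -> DKLSVMModel:
    """Multiple-kernel SVM with simplex kernel weights.

    Alternates: solve the one-vs-rest SVM dual on K = sum_n l_n K_n, then
    reweight l_n proportional to l_n * sqrt(contribution_n) and
    renormalize; stops when the weight change drops below ``tol``.
    """
    if not kernel_list:
        raise ValueError("need at least one kernel")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grams = [
        _clip_psd(gram_matrix(spec, X), spec.name)
        if spec.name in ("bessel", "spline")
        else gram_matrix(spec, X)
        for spec in kernel_list
    ]
    if max(float(np.abs(G).max()) for G in grams) == 0.0:
        raise ValueError("all-zero Gram matrix")
    N = len(grams)
    weights = np.full(N, 1.0 / N)
    svm = None
    it = 0
    for it in range(1, max_iter + 1):
        G = sum(w * Gn for w, Gn in zip(weights, grams))
        svm = KernelSVM(C=C).fit(G, y)
        if N == 1:
            break
        contrib = _kernel_contributions(svm, grams)
        if contrib.sum() == 0:
            break
        new = weights * np.sqrt(contrib)
        new /= new.sum()
        if np.abs(new - weights).max() < tol:
            weights = new
            break
        weights = new
    # final refit at the converged weights
    G = sum(w * Gn for w, Gn in zip(weights, grams))
    svm = KernelSVM(C=C).fit(G, y)
    return DKLSVMModel(
        svm=svm, kernel_list=list(kernel_list), weights=weights,
        X_train=X, classes_=np.unique(y), n_iter=it,
    )


def dkl_svm_predict(model: DKLSVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    G = sum(
        w * gram_matrix(spec, X, model.X_train)
        for w, spec in zip(model.weights, model.kernel_list)
    )
    return model.svm.predict(G)
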