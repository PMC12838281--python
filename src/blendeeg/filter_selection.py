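"""Filter-style feature selection.

Three groups of selectors, all operating on a :class:`~blendeeg.features.FeatureMatrix`:

* univariate rankers — one-way ANOVA F statistic, absolute Pearson
  correlation against the numeric label code, and plug-in mutual
  information on equal-frequency-binned features;
* FCCT — feature-correlation clustering: average-linkage hierarchical
  clustering on the 1 - |Spearman rho| distance between features, cut at a
  threshold, keeping the highest-F representative per cluster (removes
  collinear features);
* a majority-vote hybrid (HFS-MVS) over five base rankers (CFS, LASSO,
  LLCFS, Relief-F, UDFS): each base method nominates its top-k and a
  feature is kept when nominated by at least ``vote_threshold`` methods.

Every ranker is deterministic; ties are broken by ascending feature index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .features import FeatureMatrix

__all__ = [
    "FeatureMask",
    "RankedFeatures",
    "univariate_rank",
    "fcct_select",
    "base_selector_rank",
    "hfs_mvs_select",
    "BASE_SELECTOR_METHODS",
]

BASE_SELECTOR_METHODS = ("cfs", "lasso", "llcfs", "relieff", "udfs")


@dataclass
class FeatureMask:
    """Binary selection string P of length J; p_k = 1 keeps feature k."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if not set(np.unique(self.bits)) <= {0, 1}:
            raise ValueError("mask bits must be 0/1")
        if self.bits.sum() < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_json(self) -> dict:
        return {"bits": self.bits.tolist(), "selected": self.indices.tolist()}


@dataclass
class RankedFeatures:
    """Per-feature scores plus a descending-score ordering.

    ``order`` sorts scores descending with ties broken by ascending index.
    """

    scores: np.ndarray
    order: np.ndarray
    method: str

    def top_k(self, k: int) -> FeatureMask:
        if k <= 0:
            raise ValueError("k must be positive")
        bits = np.zeros(len(self.scores), dtype=int)
        bits[self.order[:k]] = 1
        return FeatureMask(bits=bits)


def _rank(scores: np.ndarray, method: str) -> RankedFeatures:
    scores = np.asarray(scores, dtype=float)
    scores = np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)
    # descending score; ties by ascending index (lexsort last key dominates)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return RankedFeatures(scores=scores, order=order, method=method)


def _binned_mi(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information (nats) after equal-frequency binning."""
    if np.ptp(x) == 0:
        return 0.0
    quantiles = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    xb = np.searchsorted(np.unique(quantiles), x)
    joint = np.zeros((xb.max() + 1, int(y.max()) + 1))
    for a, b in zip(xb, y):
        joint[a, b] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def univariate_rank(
    F: FeatureMatrix, method: str = "f_test", k: int | None = None
) -> tuple[RankedFeatures, FeatureMask | None]:
    """Score every feature independently and optionally keep the top-k.

    ``f_test``: one-way ANOVA F across classes. ``pcc``: |Pearson r|
    against the numeric label code. ``mi``: plug-in mutual information on
    10-bin equal-frequency discretized features.  Constant features score 0.
    """
    X, y = F.X, F.y
    if method == "f_test":
        with np.errstate(divide="ignore", invalid="ignore"):
            scores, _ = f_classif(X, y)
        scores = np.nan_to_num(scores, nan=0.0)
        scores[X.std(axis=0) == 0] = 0.0
    elif method == "pcc":
        yc = y.astype(float)
        sd = X.std(axis=0)
        scores = np.zeros(X.shape[1])
        nz = sd > 0
        if yc.std() > 0:
            xc = X[:, nz] - X[:, nz].mean(axis=0)
            ycen = yc - yc.mean()
            scores[nz] = np.abs(
                (xc * ycen[:, None]).mean(axis=0) / (sd[nz] * yc.std())
            )
    elif method == "mi":
        scores = np.array([_binned_mi(X[:, j], y) for j in range(X.shape[1])])
    else:
        raise ValueError(f"unknown univariate method: {method!r}")
    ranked = _rank(scores, method)
    mask = ranked.top_k(k) if k is not None else None
    return ranked, mask


def fcct_select(F: FeatureMatrix, corr_threshold: float = 0.5) -> FeatureMask:
    """Correlation-clustering filter.

    Features are clustered by average-linkage on distance 1 - |Spearman
    rho| and the dendrogram is cut at ``corr_threshold``; one
    representative per cluster is retained — the member with the highest
    univariate F statistic against the label.  A threshold near zero keeps
    (almost) every feature.
    """
    if not (0.0 < corr_threshold < 1.0):
        raise ValueError("corr_threshold must lie in (0, 1)")
    X = F.X
    J = X.shape[1]
    if J < 2:
        raise ValueError("need at least 2 features")
    rho, _ = stats.spearmanr(X)
    rho = np.atleast_2d(rho)
    rho = np.nan_to_num(rho, nan=0.0)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    clusters = hierarchy.fcluster(Z, t=corr_threshold, criterion="distance")
    fscores, _ = univariate_rank(F, "f_test")
    bits = np.zeros(J, dtype=int)
    for c in np.unique(clusters):
        members = np.flatnonzero(clusters == c)
        best = members[np.argmax(fscores.scores[members])]
        bits[best] = 1
    return FeatureMask(bits=bits)


# ---------------------------------------------------------------------------
# Five base rankers behind one contract


def _corr_abs(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def _cfs_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature CFS merit: class correlation penalized by average
    redundancy with the other features."""
    J = X.shape[1]
    yc = y.astype(float)
    rcf = np.array([_corr_abs(X[:, j], yc) for j in range(J)])
    C = np.abs(np.nan_to_num(np.corrcoef(X, rowvar=False), nan=0.0))
    if C.ndim == 0:
        C = np.array([[1.0]])
    rff = (C.sum(axis=1) - 1.0) / max(J - 1, 1)
    return rcf / np.sqrt(1.0 + rff)


def _lasso_scores(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """|coefficient| of an L1 one-vs-rest logistic fit at a regularization
    chosen (by bisection on C) to give roughly k nonzero features."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    def fit(C: float) -> np.ndarray:
        clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=500
        )
        coefs = []
        for cls in np.unique(y):
            clf.fit(Z, (y == cls).astype(int))
            coefs.append(np.abs(clf.coef_[0]))
        return np.max(coefs, axis=0)

    lo, hi = 1e-3, 10.0
    best = fit(hi)
    for _ in range(12):
        mid = np.sqrt(lo * hi)
        s = fit(mid)
        nnz = int((s > 1e-9).sum())
        if nnz >= k:
            best, hi = s, mid
        else:
            lo = mid
        if hi / lo < 1.1:
            break
    return best


def _relieff_scores(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 5,
    n_samples: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Relief-F weights: hit/miss nearest-neighbour updates, misses
    weighted by class priors."""
    rng = np.random.default_rng(seed)
    n, J = X.shape
    span = np.ptp(X, axis=0)
    span[span == 0] = 1.0
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    nn_by_class = {}
    for c in classes:
        pts = X[y == c]
        nn_by_class[c] = (
            NearestNeighbors(
                n_neighbors=min(n_neighbors + 1, len(pts))
            ).fit(pts),
            pts,
        )
    idx = np.arange(n)
    if n_samples is not None and n_samples < n:
        idx = rng.choice(n, size=n_samples, replace=False)
    w = np.zeros(J)
    for i in idx:
        xi, ci = X[i], y[i]
        for c in classes:
            nn, pts = nn_by_class[c]
            kq = min(n_neighbors + (1 if c == ci else 0), len(pts))
            _, neigh = nn.kneighbors(xi[None], n_neighbors=kq)
            neigh = neigh[0]
            if c == ci:
                neigh = neigh[1:]  # drop self
            if len(neigh) == 0:
                continue
            diff = np.abs(pts[neigh] - xi[None]) / span[None]
            mean_diff = diff.mean(axis=0)
            if c == ci:
                w -= mean_diff / len(idx)
            else:
                w += (
                    priors[c] / (1.0 - priors[ci]) * mean_diff / len(idx)
                )
    return w


def _llcfs_scores(
    X: np.ndarray, y: np.ndarray, n_neighbors: int = 5, n_iter: int = 4
) -> np.ndarray:
    """Iterative local-learning weights on a kNN graph.

    Feature weights and the graph are refined alternately: the graph is
    built under the current weighted metric, and each feature is rescored
    by how smooth it is across graph edges relative to its global spread
    (a Laplacian-score-style criterion; smoother on the cluster structure
    means more discriminative here).  Small-scale formulation.
    """
    n, J = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    w = np.ones(J) / J
    for _ in range(n_iter):
        Zw = Z * np.sqrt(w)[None, :]
        nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(Zw)
        _, neigh = nn.kneighbors(Zw)
        neigh = neigh[:, 1:]
        # mean squared feature difference across graph edges
        edge_var = np.zeros(J)
        for i in range(n):
            edge_var += ((Z[neigh[i]] - Z[i][None]) ** 2).mean(axis=0)
        edge_var /= n
        score = 1.0 / (edge_var + 1e-12)
        w = score / score.sum()
    return w


def _udfs_scores(
    X: np.ndarray,
    y: np.ndarray,
    n_neighbors: int = 5,
    gamma: float = 0.1,
    n_iter: int = 10,
) -> np.ndarray:
    """L2,1-regularized discriminative scores (batch-mode selection).

    Minimizes tr(W' M W) + gamma ||W||_{2,1} with W'W = I, where M is the
    kNN-graph Laplacian quadratic form of the standardized data; solved by
    the usual iteratively reweighted eigen-decomposition.  Scores are the
    row norms of W.  Small-scale formulation.
    """
    n, J = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(Z)
    graph = nn.kneighbors_graph(Z, mode="connectivity")
    W_adj = ((graph + graph.T) > 0).astype(float).toarray()
    np.fill_diagonal(W_adj, 0.0)
    L = np.diag(W_adj.sum(axis=1)) - W_adj
    M = Z.T @ L @ Z / n
    c = min(len(np.unique(y)), J)
    D = np.eye(J)
    W = None
    for _ in range(n_iter):
        vals, vecs = np.linalg.eigh(M + gamma * D)
        W = vecs[:, :c]
        row_norms = np.sqrt((W**2).sum(axis=1))
        D = np.diag(1.0 / (2.0 * np.maximum(row_norms, 1e-8)))
    return np.sqrt((W**2).sum(axis=1))


def base_selector_rank(
    F: FeatureMatrix, method: str, k: int | None = None, seed: int = 0
) -> RankedFeatures:
    """Full descending ranking from one of the five base methods."""
    X, y = F.X, F.y
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if method == "cfs":
        scores = _cfs_scores(X, y)
    elif method == "lasso":
        scores = _lasso_scores(X, y, k if k is not None else max(X.shape[1] // 5, 1))
    elif method == "relieff":
        scores = _relieff_scores(X, y, seed=seed)
    elif method == "llcfs":
        scores = _llcfs_scores(X, y)
    elif method == "udfs":
        scores = _udfs_scores(X, y)
    else:
        raise ValueError(f"unknown base selector: {method!r}")
    return _rank(scores, method)


def hfs_mvs_select(
    F: FeatureMatrix, k: int, vote_threshold: int = 3, seed: int = 0
) -> FeatureMask:
    """Hybrid feature selection by majority vote.

    Each of the five base rankers nominates its top-k features; a feature
    is selected when nominated by at least ``vote_threshold`` of them.  If
    that set is empty the features with the maximal vote count are
    returned instead (the mask is never empty).
    """
    if not (1 <= vote_threshold <= len(BASE_SELECTOR_METHODS)):
        raise ValueError("vote_threshold must lie in 1..5")
    votes = np.zeros(F.n_features, dtype=int)
    for method in BASE_SELECTOR_METHODS:
        ranked = base_selector_rank(F, method, k=k, seed=seed)
        votes[ranked.order[:k]] += 1
    bits = (votes >= vote_threshold).astype(int)
    if bits.sum() == 0:
        bits = (votes == votes.max()).astype(int)
    return FeatureMask(bits=bits)
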