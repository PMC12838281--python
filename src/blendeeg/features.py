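"""Feature extraction: wavelet subband statistics, raw statistical
descriptors, and fuzzy C-means (FCM) membership features.

Three feature families are produced from epoched EEG:

* ``dwt`` — a db4 discrete wavelet transform decomposes each channel epoch
  into detail subbands D1..DL and the final approximation AL (level 4 at
  250 Hz makes the subbands approximate the clinical delta/theta/alpha/beta
  split), and five statistical descriptors are computed per subband;
* ``statistical`` — the same five descriptors on the raw channel epochs;
* ``fcm`` — fuzzy C-means is fitted on the dwt-feature matrix and each
  epoch is described by its C cluster memberships plus its C distances to
  the cluster centers.

The five descriptors are average power (mean of squares), population
standard deviation, kurtosis, skewness and mean absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from .fixtures import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "WaveletDecomposition",
    "FCMModel",
    "FeatureMatrix",
    "STAT_FEATURE_NAMES",
    "dwt_decompose",
    "dwt_reconstruct",
    "statistical_features",
    "fcm_fit",
    "fcm_membership",
    "build_feature_matrix",
    "save_feature_csv",
    "load_feature_csv",
]

STAT_FEATURE_NAMES = ("power", "std", "kurtosis", "skewness", "mav")


# ---------------------------------------------------------------------------
# Discrete wavelet transform


@dataclass
class WaveletDecomposition:
    """Dyadic DWT of one signal: detail coefficients per level plus the
    final approximation.

    ``detail_coeffs[0]`` is D1 (finest, highest frequency half-band),
    ``detail_coeffs[-1]`` is DL; ``scaling_coeffs`` is the level-L
    approximation AL.
    """

    scaling_coeffs: np.ndarray
    detail_coeffs: list[np.ndarray]
    wavelet_name: str
    levels: int
    mode: str = "symmetric"

    @property
    def subbands(self) -> dict[str, np.ndarray]:
        bands = {f"D{j + 1}": d for j, d in enumerate(self.detail_coeffs)}
        bands[f"A{self.levels}"] = self.scaling_coeffs
        return bands


def dwt_decompose(
    signal: np.ndarray, wavelet_name: str = "db4", levels: int = 4
) -> WaveletDecomposition:
    """Cascade low/high-pass filtering with dyadic downsampling.

    Raises if the signal is too short for the requested depth, naming the
    maximum feasible level.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    wavelet = pywt.Wavelet(wavelet_name)
    max_level = pywt.dwt_max_level(len(signal), wavelet.dec_len)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > max_level:
        raise ValueError(
            f"signal of length {len(signal)} supports at most "
            f"level {max_level} with {wavelet_name}, got {levels}"
        )
    coeffs = pywt.wavedec(signal, wavelet, mode="symmetric", level=levels)
    approx = coeffs[0]
    # pywt returns [A_L, D_L, ..., D_1]; store details finest-first
    details = list(coeffs[1:])[::-1]
    return WaveletDecomposition(
        scaling_coeffs=approx,
        detail_coeffs=details,
        wavelet_name=wavelet_name,
        levels=levels,
    )


def dwt_reconstruct(dec: WaveletDecomposition, length: int | None = None) -> np.ndarray:
    """Inverse transform; exact (to machine precision) for orthogonal wavelets."""
    coeffs = [dec.scaling_coeffs] + dec.detail_coeffs[::-1]
    rec = pywt.waverec(coeffs, dec.wavelet_name, mode=dec.mode)
    if length is not None:
        rec = rec[:length]
    return rec


# ---------------------------------------------------------------------------
# Statistical descriptors


def statistical_features(v: np.ndarray) -> tuple[np.ndarray, bool]:
    """Five-point statistical summary of a vector.

    Returns ``(features, degenerate)`` where features is
    (average power, population std, kurtosis, skewness, mean absolute value).
    Kurtosis is the plain standardized fourth moment (3 for a Gaussian).
    Zero-variance input yields kurtosis = skewness = 0 with the degenerate
    flag set.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 4:
        raise ValueError("need at least 4 samples for kurtosis")
    power = float(np.mean(v**2))
    mav = float(np.mean(np.abs(v)))
    mu = v.mean()
    centered = v - mu
    var = float(np.mean(centered**2))
    std = float(np.sqrt(var))
    if var <= 0.0:
        return np.array([power, 0.0, 0.0, 0.0, mav]), True
    skew = float(np.mean(centered**3) / var**1.5)
    kurt = float(np.mean(centered**4) / var**2)
    return np.array([power, std, kurt, skew, mav]), False


# ---------------------------------------------------------------------------
# Fuzzy C-means


@dataclass
class FCMModel:
    """A fitted fuzzy C-means clustering.

    Minimizes Z = sum_i sum_z q_iz^g ||a_i - C_z||^2 by alternating the
    membership update q_iz = 1 / sum_k (d_iz / d_ik)^(2/(g-1)) and the
    center update C_z = sum_i q_iz^g a_i / sum_i q_iz^g.  Membership rows
    sum to one; the objective is non-increasing across iterations.
    """

    centers: np.ndarray
    fuzziness: float
    memberships: np.ndarray
    n_clusters: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _fcm_memberships(
    X: np.ndarray, centers: np.ndarray, g: float
) -> np.ndarray:
    """Membership update; a point coincident with a center gets the
    indicator membership of that center (the analytic limit)."""
    d2 = np.maximum(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 0.0
    )
    q = np.empty_like(d2)
    zero_rows = (d2 < 1e-24).any(axis=1)
    expo = 1.0 / (g - 1.0)
    nz = ~zero_rows
    if nz.any():
        # q_iz = 1 / sum_k (d_iz/d_ik)^(1/(g-1)) on squared distances
        inv = d2[nz] ** (-expo)
        q[nz] = inv / inv.sum(axis=1, keepdims=True)
    for i in np.where(zero_rows)[0]:
        row = np.zeros(centers.shape[0])
        row[np.argmin(d2[i])] = 1.0
        q[i] = row
    return q


def _fcm_objective(X, centers, q, g) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(((q**g) * d2).sum())


def fcm_fit(
    X: np.ndarray,
    n_clusters: int = 3,
    fuzziness: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | np.random.Generator = 0,
) -> FCMModel:
    """Fit fuzzy C-means by alternating optimization.

    Centers are initialized from random distinct data rows; duplicate
    centers after initialization are jittered.  Iterates until the maximum
    absolute membership change falls below ``tol`` or ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    C, g = n_clusters, float(fuzziness)
    if C < 2:
        raise ValueError("need at least 2 clusters")
    if g <= 1.0:
        raise ValueError("fuzziness must exceed 1")
    if X.shape[0] < C:
        raise ValueError("need at least n_clusters data rows")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    idx = rng.choice(X.shape[0], size=C, replace=False)
    centers = X[idx].copy()
    # re-seeded jitter for coincident initial centers
    for _ in range(10):
        dists = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(dists, np.inf)
        if dists.min() > 1e-18:
            break
        scale = X.std() if X.std() > 0 else 1.0
        centers += rng.normal(0.0, 1e-3 * scale, size=centers.shape)

    q = _fcm_memberships(X, centers, g)
    trace = [_fcm_objective(X, centers, q, g)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        qg = q**g
        centers = (qg.T @ X) / qg.sum(axis=0)[:, None]
        q_new = _fcm_memberships(X, centers, g)
        trace.append(_fcm_objective(X, centers, q_new, g))
        delta = np.abs(q_new - q).max()
        q = q_new
        if delta < tol:
            converged = True
            break
    return FCMModel(
        centers=centers,
        fuzziness=g,
        memberships=q,
        n_clusters=C,
        objective=trace[-1],
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def fcm_membership(model: FCMModel, X_new: np.ndarray) -> np.ndarray:
    """Memberships of new points under frozen centers; rows sum to one."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[:, None]
    if X_new.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.centers.shape[1]} "
            f"features, got {X_new.shape[1]}"
        )
    return _fcm_memberships(X_new, model.centers, model.fuzziness)


# ---------------------------------------------------------------------------
# Feature-matrix assembly


@dataclass
class FeatureMatrix:
    """Samples x features with labels, names and per-sample subject ids."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("rows(X) must equal len(y)")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("one name per feature required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            X=self.X[:, mask],
            y=self.y,
            feature_names=[n for n, m in zip(self.feature_names, mask) if m],
            subject_ids=self.subject_ids,
            metadata=dict(self.metadata),
        )


def _epoch_dwt_features(
    epochs: EpochSet, wavelet: str, levels: int
) -> tuple[np.ndarray, list[str]]:
    n_epochs, n_channels, _ = epochs.epochs.shape
    sample_dec = dwt_decompose(epochs.epochs[0, 0], wavelet, levels)
    band_names = list(sample_dec.subbands.keys())
    names = [
        f"ch{c}_{band}_{stat}"
        for c in range(n_channels)
        for band in band_names
        for stat in STAT_FEATURE_NAMES
    ]
    X = np.empty((n_epochs, len(names)))
    for i in range(n_epochs):
        row = []
        for c in range(n_channels):
            dec = dwt_decompose(epochs.epochs[i, c], wavelet, levels)
            for band in band_names:
                feats, _ = statistical_features(dec.subbands[band])
                row.append(feats)
        X[i] = np.concatenate(row)
    return X, names


def build_feature_matrix(
    epochs: EpochSet,
    family: str = "dwt",
    wavelet: str = "db4",
    levels: int = 4,
    n_clusters: int = 3,
    fuzziness: float = 2.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Assemble one of the three feature families from an epoch set.

    ``dwt``: 5 statistics per wavelet subband per channel.
    ``statistical``: 5 statistics per channel on the raw epoch.
    ``fcm``: FCM fitted on the dwt features; each epoch is represented by
    its C memberships and C center distances (2C features).

    Epochs producing any non-finite feature are dropped (count logged).
    """
    if epochs.n_epochs == 0:
        raise ValueError("epoch set is empty")
    if family == "dwt":
        X, names = _epoch_dwt_features(epochs, wavelet, levels)
    elif family == "statistical":
        n_epochs, n_channels, _ = epochs.epochs.shape
        names = [
            f"ch{c}_raw_{stat}"
            for c in range(n_channels)
            for stat in STAT_FEATURE_NAMES
        ]
        X = np.empty((n_epochs, len(names)))
        for i in range(n_epochs):
            X[i] = np.concatenate(
                [
                    statistical_features(epochs.epochs[i, c])[0]
                    for c in range(n_channels)
                ]
            )
    elif family == "fcm":
        base, _ = _epoch_dwt_features(epochs, wavelet, levels)
        # standardize so no single high-variance statistic dominates distance
        mu, sd = base.mean(axis=0), base.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (base - mu) / sd
        model = fcm_fit(
            Z, n_clusters=n_clusters, fuzziness=fuzziness, seed=seed
        )
        q = model.memberships
        dists = np.sqrt(
            ((Z[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
        )
        X = np.hstack([q, dists])
        names = [f"fcm_membership_c{z}" for z in range(n_clusters)] + [
            f"fcm_dist_c{z}" for z in range(n_clusters)
        ]
    else:
        raise ValueError(f"unknown feature family: {family!r}")

    finite = np.isfinite(X).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning("dropped %d epochs with non-finite features", n_dropped)
    return FeatureMatrix(
        X=X[finite],
        y=epochs.labels[finite],
        feature_names=names,
        subject_ids=epochs.subject_ids[finite],
        metadata={
            "family": family,
            "wavelet": wavelet,
            "levels": levels,
            "std_divisor": "population",
        },
    )


def save_feature_csv(fm: FeatureMatrix, path) -> None:
    """Write as delimited text: header row, one column per feature, final
    column ``label`` (the dialect every selector and classifier reads)."""
    df = pd.DataFrame(fm.X, columns=fm.feature_names)
    df["label"] = fm.y
    df.to_csv(path, index=False)


def load_feature_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return FeatureMatrix(
        X=df.to_numpy(dtype=float),
        y=y,
        feature_names=list(df.columns),
        subject_ids=np.array([f"row{i}" for i in range(len(y))], dtype=object),
    )
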