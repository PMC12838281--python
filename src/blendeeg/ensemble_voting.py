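"""Soft-voting ensemble of heterogeneous classifiers.

Four probabilistic members — a decision tree, Gaussian naive Bayes, a
multinomial logistic GLM (logit link) and an SVM — are trained
independently on the same data; predictions combine their class
probabilities by weighted summation and the class with the largest
accumulated probability wins.  This is the multi-class generalization of
the binary positive/negative probability-sum rule: per class, accumulate
weighted member probabilities and take the argmax, ties broken by the
lowest class index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "EnsembleModel",
    "soft_vote",
    "ensemble_fit",
    "ensemble_predict",
    "DEFAULT_MEMBERS",
]

DEFAULT_MEMBERS = ("dt", "nb", "glm", "svm")


def soft_vote(
    prob_rows: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-member class probabilities by weighted summation.

    ``prob_rows`` has shape (members, classes) for a single sample or
    (members, samples, classes); each member row must sum to one (1e-6).
    Returns (predicted class index/indices, renormalized averaged
    probabilities).  Ties go to the lowest class index; the result is
    invariant to uniform scaling of the weights.
    """
    P = np.asarray(prob_rows, dtype=float)
    single = P.ndim == 2
    if single:
        P = P[:, None, :]
    if P.ndim != 3:
        raise ValueError("prob_rows must be (members, classes) or (members, samples, classes)")
    n_members, _, n_classes = P.shape
    sums = P.sum(axis=2)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("each member's probabilities must sum to 1 (±1e-6)")
    if weights is None:
        weights = np.ones(n_members)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_members,):
        raise ValueError("one weight per member required")
    acc = np.tensordot(weights, P, axes=(0, 0))  # (samples, classes)
    # argmax with ties broken by the lowest class index (argmax is first-max)
    pred = np.argmax(acc, axis=1)
    avg = acc / acc.sum(axis=1, keepdims=True)
    if single:
        return pred[0], avg[0]
    return pred, avg


class _SVMProbMember:
    """SVM member whose probabilities are a softmax over one-vs-rest
    decision values (no Platt calibration)."""

    def __init__(self, C: float = 1.0, kernel: str = "rbf"):
        self.clf = SVC(C=C, kernel=kernel, decision_function_shape="ovr")

    def fit(self, X, y):
        self.clf.fit(X, y)
        self.classes_ = self.clf.classes_
        return self

    def predict_proba(self, X):
        dec = self.clf.decision_function(X)
        if dec.ndim == 1:
            dec = np.column_stack([-dec, dec])
        z = dec - dec.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)


def _make_member(name: str, seed: int):
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if name == "nb":
        return GaussianNB()
    if name == "glm":
        # multinomial logistic regression, logit link
        return LogisticRegression(max_iter=1000)
    if name == "svm":
        return _SVMProbMember()
    raise ValueError(f"unknown ensemble member: {name!r}")


@dataclass
class EnsembleModel:
    members: list
    member_names: list[str]
    weights: np.ndarray
    classes_: np.ndarray = field(default=None)


def ensemble_fit(
    X: np.ndarray,
    y: np.ndarray,
    member_spec: tuple[str, ...] = DEFAULT_MEMBERS,
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train the members independently on identical data.

    A member that fails to fit is excluded with a warning provided at
    least two members remain; fewer than two is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(member_spec) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    classes = np.unique(y)
    fitted, names, kept_w = [], [], []
    w_in = (
        np.ones(len(member_spec)) if weights is None else np.asarray(weights, float)
    )
    for name, w in zip(member_spec, w_in):
        member = _make_member(name, seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                member.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - member failure is expected path
            warnings.warn(f"ensemble member {name!r} failed to fit: {exc}", stacklevel=2)
            continue
        fitted.append(member)
        names.append(name)
        kept_w.append(w)
    if not fitted:
        raise ValueError("no ensemble member could be fitted")
    if len(fitted) < 2:
        warnings.warn(
            "only one ensemble member survived; ensemble reduces to it",
            stacklevel=2,
        )
    return EnsembleModel(
        members=fitted, member_names=names,
        weights=np.asarray(kept_w, dtype=float), classes_=classes,
    )


def ensemble_predict(
    model: EnsembleModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-voted labels and averaged probabilities."""
    X = np.asarray(X, dtype=float)
    probs = []
    for member in model.members:
        p = member.predict_proba(X)
        # align member class columns to the ensemble class list
        full = np.zeros((X.shape[0], len(model.classes_)))
        member_classes = member.classes_
        for ci, c in enumerate(member_classes):
            full[:, int(np.searchsorted(model.classes_, c))] = p[:, ci]
        probs.append(full)
    P = np.stack(probs)  # (members, samples, classes)
    pred_idx, avg = soft_vote(P, model.weights)
    return model.classes_[pred_idx], avg
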