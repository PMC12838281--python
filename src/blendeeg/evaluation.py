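"""Cross-validated benchmarking of the {feature family x selector x
classifier} grid, with agreement statistics.

The protocol is stratified 10-fold cross-validation at epoch level, with
feature selection fitted inside each training fold only (no selection
leakage into the held-out fold).  Because epochs inherit their subject's
label, epoch-level folds can place epochs of one subject in both train and
test; an optional subject-grouped mode keeps subjects intact across the
split for a stricter estimate.

Accuracy is reported as mean fold accuracy in percent; agreement is
summarized by Cohen's kappa (chance-corrected agreement from the confusion
matrix) and paired score vectors are compared by the two-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from . import classifiers_boost as cb
from . import classifiers_pls_kernels as cpk
from . import ensemble_voting as ev
from . import filter_selection as fs
from . import metaheuristics as mh
from .features import FeatureMatrix

__all__ = [
    "CVResult",
    "GridResult",
    "cohen_kappa",
    "agreement_stats",
    "make_selector",
    "make_classifier",
    "cross_validate",
    "run_benchmark_grid",
    "SELECTOR_NAMES",
    "CLASSIFIER_NAMES",
]

SELECTOR_NAMES = (
    "none", "ftest", "pcc", "mi", "fcct", "hfsmvs", "gwo", "ssopso", "boa",
)
CLASSIFIER_NAMES = (
    "smogbm", "gbm", "dklsvm", "catboost", "xgboost", "plslda",
    "plssvm_polynomial", "plssvm_linear", "plssvm_laplacian",
    "plssvm_bessel", "plssvm_spline", "ensemble", "knn", "majority",
)


# ---------------------------------------------------------------------------
# Agreement statistics


def cohen_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("equal lengths required")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    n = len(y_true)
    cm = np.zeros((len(classes), len(classes)))
    lut = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[lut[t], lut[p]] += 1
    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def agreement_stats(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    paired_scores_a: np.ndarray | None = None,
    paired_scores_b: np.ndarray | None = None,
) -> dict:
    """Cohen's kappa of the predictions, plus a two-sided Wilcoxon
    signed-rank p-value on the paired score vectors when given (exact null
    for n <= 25, normal approximation with tie correction otherwise).
    All-identical paired differences leave the Wilcoxon undefined (NaN).
    """
    out = {"kappa": cohen_kappa(y_true, y_pred), "wilcoxon_p": None}
    if paired_scores_a is not None and paired_scores_b is not None:
        a = np.asarray(paired_scores_a, dtype=float)
        b = np.asarray(paired_scores_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired score vectors must have equal length")
        diffs = a - b
        if np.all(diffs == 0):
            out["wilcoxon_p"] = float("nan")
        else:
            method = "exact" if len(a) <= 25 and not np.any(diffs == 0) else "approx"
            _, p = stats.wilcoxon(a, b, alternative="two-sided", method=method)
            out["wilcoxon_p"] = float(p)
    return out


# ---------------------------------------------------------------------------
# Selector / classifier registries


def make_selector(name: str, **params):
    """Return ``select(F: FeatureMatrix, seed) -> FeatureMask | None``."""
    name = name.lower()
    if name == "none":
        return lambda F, seed=0: None
    if name in ("ftest", "f_test", "pcc", "mi"):
        method = "f_test" if name in ("ftest", "f_test") else name
        k = params.get("k", 10)

        def select(F: FeatureMatrix, seed: int = 0):
            _, mask = fs.univariate_rank(F, method, k=min(k, F.n_features))
            return mask

        return select
    if name == "fcct":
        threshold = params.get("corr_threshold", 0.5)
        return lambda F, seed=0: fs.fcct_select(F, corr_threshold=threshold)
    if name == "hfsmvs":
        k = params.get("k", 10)
        vote = params.get("vote_threshold", 3)
        return lambda F, seed=0: fs.hfs_mvs_select(
            F, k=min(k, F.n_features), vote_threshold=vote, seed=seed
        )
    if name in ("gwo", "ssopso", "sso_pso", "boa"):
        algo = {"ssopso": "sso_pso"}.get(name, name)
        pop = params.get("pop", 15)
        iters = params.get("iters", 15)
        budget = params.get("budget")
        spec = params.get("spec") or mh.FitnessSpec()

        def select(F: FeatureMatrix, seed: int = 0):
            mask, _ = mh.wrapper_select(
                F.X, F.y, algorithm=algo, spec=spec,
                pop=pop, iters=iters, budget=budget, seed=seed,
            )
            return mask

        return select
    raise ValueError(f"unknown selector: {name!r}")


class _MajorityClassifier:
    def fit(self, X, y):
        classes, counts = np.unique(y, return_counts=True)
        self.label_ = classes[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.label_)


class _Clf:
    """Wrap fit/predict closures into the common classifier protocol."""

    def __init__(self, fit_fn):
        self._fit_fn = fit_fn

    def fit(self, X, y):
        self._predict = self._fit_fn(X, y)
        return self

    def predict(self, X):
        return self._predict(X)


def make_classifier(name: str, seed: int = 0, **params):
    """Instantiate a classifier by registry name.

    Unavailable optional backends raise
    :class:`~blendeeg.classifiers_boost.BackendUnavailableError`.
    """
    name = name.lower()
    if name == "majority":
        return _MajorityClassifier()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=params.get("k", 5))
    if name == "gbm":
        def fit(X, y):
            model = cb.gbm_fit(X, y, {**params, "seed": seed})
            return lambda Xt: model.classes_[
                np.argmax(cb.gbm_predict(model, Xt), axis=1)
            ]
        return _Clf(fit)
    if name == "smogbm":
        cfg = params.get("smo_config") or cb.SMOConfig(
            population=6, iterations=3, local_leader_limit=3,
            global_leader_limit=2, seed=seed,
        )
        def fit(X, y):
            model, _, _ = cb.smo_gbm_train(X, y, smo_config=cfg, seed=seed)
            return lambda Xt: model.classes_[
                np.argmax(cb.gbm_predict(model, Xt), axis=1)
            ]
        return _Clf(fit)
    if name in ("catboost", "xgboost"):
        spec = cb.BoostingBackendSpec(backend=name, hyperparameters=params)
        def fit(X, y):
            model = cb.backend_fit(X, y, spec)
            return model.predict
        return _Clf(fit)
    if name == "plslda":
        H = params.get("n_components", 10)
        def fit(X, y):
            model = cpk.pls_lda_fit(X, y, n_components=min(H, X.shape[1]))
            return lambda Xt: cpk.pls_lda_predict(model, Xt)
        return _Clf(fit)
    if name.startswith("plssvm"):
        kernel = params.get("kernel") or name.split("_", 1)[1]
        spec = cpk.KernelSpec(
            kernel,
            degree=params.get("degree", 2),
            sigma=params.get("sigma", 1.0),
        )
        H = params.get("n_components", 10)
        C = params.get("C", 1.0)
        def fit(X, y):
            model = cpk.pls_svm_fit(
                X, y, n_components=min(H, X.shape[1]), spec=spec, C=C
            )
            return lambda Xt: cpk.pls_svm_predict(model, Xt)
        return _Clf(fit)
    if name == "dklsvm":
        kernels = params.get("kernels") or [
            cpk.KernelSpec("linear"),
            cpk.KernelSpec("polynomial", degree=2),
            cpk.KernelSpec("laplacian", sigma=1.0),
        ]
        C = params.get("C", 1.0)
        def fit(X, y):
            model = cpk.dkl_svm_fit(X, y, kernels, C=C)
            return lambda Xt: cpk.dkl_svm_predict(model, Xt)
        return _Clf(fit)
    if name == "ensemble":
        members = params.get("members", ev.DEFAULT_MEMBERS)
        def fit(X, y):
            model = ev.ensemble_fit(X, y, member_spec=members, seed=seed)
            return lambda Xt: ev.ensemble_predict(model, Xt)[0]
        return _Clf(fit)
    raise ValueError(f"unknown classifier: {name!r}")


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    """Per-fold accuracies (fractions), mean accuracy in percent, Cohen's
    kappa of the pooled out-of-fold predictions."""

    fold_accuracies: np.ndarray
    mean_accuracy: float            # percent
    kappa: float
    y_true: np.ndarray
    y_pred: np.ndarray
    folds: int
    seed: int


def cross_validate(
    selector,
    classifier_name: str,
    F: FeatureMatrix,
    folds: int = 10,
    seed: int = 0,
    grouped: bool = False,
    classifier_params: dict | None = None,
) -> CVResult:
    """Stratified (or subject-grouped) k-fold evaluation of one pipeline.

    ``selector`` is either a registry name or a ``select(F, seed)``
    callable; it is fitted inside each training fold only.  Classes with
    fewer samples than ``folds`` reduce the fold count with a warning.
    ``classifier_name`` may also be a zero-argument factory returning a
    fit/predict object (a fresh instance is built per fold).
    """
    if isinstance(selector, str):
        selector = make_selector(selector)
    classifier_params = classifier_params or {}
    X, y = F.X, F.y
    _, counts = np.unique(y, return_counts=True)
    n_folds = min(folds, counts.min())
    if n_folds < folds:
        warnings.warn(
            f"smallest class has {counts.min()} samples; using {n_folds} folds",
            stacklevel=2,
        )
    if n_folds < 2:
        raise ValueError("need at least 2 samples per class")

    if grouped:
        splitter = GroupKFold(n_splits=min(n_folds, len(np.unique(F.subject_ids))))
        split = splitter.split(X, y, groups=F.subject_ids)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)

    accs, y_true_all, y_pred_all = [], [], []
    for fold_i, (tr, te) in enumerate(split):
        F_tr = FeatureMatrix(
            X=X[tr], y=y[tr],
            feature_names=F.feature_names,
            subject_ids=F.subject_ids[tr],
        )
        mask = selector(F_tr, seed=seed * 1000 + fold_i)
        if mask is not None:
            cols = mask.indices
        else:
            cols = np.arange(X.shape[1])
        if callable(classifier_name) and not isinstance(classifier_name, str):
            clf = classifier_name()
        else:
            clf = make_classifier(classifier_name, seed=seed, **classifier_params)
        clf.fit(X[np.ix_(tr, cols)], y[tr])
        pred = np.asarray(clf.predict(X[np.ix_(te, cols)]))
        accs.append(float(np.mean(pred == y[te])))
        y_true_all.append(y[te])
        y_pred_all.append(pred)

    accs = np.array(accs)
    y_true_all = np.concatenate(y_true_all)
    y_pred_all = np.concatenate(y_pred_all)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean() * 100.0),
        kappa=cohen_kappa(y_true_all, y_pred_all),
        y_true=y_true_all,
        y_pred=y_pred_all,
        folds=n_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Benchmark grid


@dataclass
class GridResult:
    """One accuracy table per selector: rows = feature families, columns =
    classifiers, cells = mean CV accuracy (percent, 2 decimals)."""

    tables: dict[str, pd.DataFrame]
    manifest: dict = field(default_factory=dict)

    @property
    def manifest_hash(self) -> str:
        payload = json.dumps(self.manifest, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sel, df in self.tables.items():
            df.to_csv(out / f"accuracy_{sel}.csv")
            (out / f"accuracy_{sel}.md").write_text(df.to_markdown())
        manifest = dict(self.manifest)
        manifest["hash"] = self.manifest_hash
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_benchmark_grid(
    feature_matrices: dict[str, FeatureMatrix],
    selectors: dict[str, dict],
    classifiers: dict[str, dict],
    folds: int = 10,
    seed: int = 0,
) -> GridResult:
    """Full Cartesian grid {family x selector x classifier} with shared
    fold seeds.  An unavailable optional backend marks its cells
    ``unavailable`` and the grid continues."""
    tables: dict[str, pd.DataFrame] = {}
    cells = {}
    for sel_name, sel_params in selectors.items():
        rows = {}
        for fam, F in feature_matrices.items():
            row = {}
            for clf_name, clf_params in classifiers.items():
                try:
                    res = cross_validate(
                        make_selector(sel_name, **sel_params),
                        clf_name, F, folds=folds, seed=seed,
                        classifier_params=clf_params,
                    )
                    row[clf_name] = round(res.mean_accuracy, 2)
                    cells[(sel_name, fam, clf_name)] = res.mean_accuracy
                except cb.BackendUnavailableError:
                    row[clf_name] = None
                    cells[(sel_name, fam, clf_name)] = "unavailable"
            rows[fam] = row
        tables[sel_name] = pd.DataFrame(rows).T
    manifest = {
        "seed": seed,
        "folds": folds,
        "selectors": {k: dict(v) for k, v in selectors.items()},
        "classifiers": {k: dict(v) for k, v in classifiers.items()},
        "cells": {"|".join(k): v for k, v in cells.items()},
    }
    return GridResult(tables=tables, manifest=manifest)
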