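"""Classifier training/evaluation: repeated stratified cross-validation with
random negative resampling, rank-based AUC, and candidate-pair prediction.

The evaluation protocol: a balanced matrix (all known positives + an equal
number of freshly sampled negatives) is built once per repeat, split into
stratified folds, and each fold is scored by a classifier trained on the
rest.  Fold AUCs are averaged into a repeat AUC and repeat AUCs into the
grand mean.  Every random choice (negative draws, fold shuffles, classifier
internals) derives from one seed, so a run is fully reproducible.

Backends follow a minimal contract — ``fit(X, y)`` then ``score(X) ->
scores`` — and the three reference backends (a C4.5-style decision tree, a
random forest, and a multilayer perceptron) wrap scikit-learn estimators
with library-default hyperparameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import mutual_info_classif
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .entities import AssociationSet, Catalogs
from .exceptions import ParameterError
from .features import (
    FEATURE_NAMES,
    ADJACENCY_FEATURES,
    MODULE_FEATURES,
    LABEL_POSITIVE,
    build_feature_vector,
    build_training_matrix,
)
from .network import GeneNetwork, PathScoreConfig

FEATURE_SETS = {
    "all": tuple(FEATURE_NAMES),
    "adjacency": tuple(ADJACENCY_FEATURES),
    "module": tuple(MODULE_FEATURES),
}


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative).

    Ties count one half.  Equivalent to the area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# -- classifier backends ---------------------------------------------------


class SklearnBackend:
    """fit/score wrapper over a scikit-learn probabilistic classifier."""

    def __init__(self, name: str, estimator):
        self.name = name
        self.estimator = estimator
        self.feature_names_: tuple | None = None

    def fit(self, features: pd.DataFrame, labels) -> "SklearnBackend":
        self.feature_names_ = tuple(features.columns)
        y = np.asarray(labels, dtype=int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.estimator.fit(features.to_numpy(), y)
        return self

    def score(self, features: pd.DataFrame) -> np.ndarray:
        if self.feature_names_ is None:
            raise ParameterError("backend is not fitted")
        if tuple(features.columns) != self.feature_names_:
            raise ParameterError(
                "feature schema mismatch: model was trained on different columns"
            )
        proba = self.estimator.predict_proba(features.to_numpy())
        positive = list(self.estimator.classes_).index(1)
        return proba[:, positive]


class ConstantBackend:
    """Uninformative baseline: the same score for every pair (AUC 0.5)."""

    name = "constant"

    def __init__(self, value: float = 0.5):
        self.value = value
        self.feature_names_: tuple | None = None

    def fit(self, features: pd.DataFrame, labels) -> "ConstantBackend":
        self.feature_names_ = tuple(features.columns)
        return self

    def score(self, features: pd.DataFrame) -> np.ndarray:
        return np.full(len(features), self.value)


def make_backend(name: str, seed: int = 0):
    """Instantiate a named backend with library-default hyperparameters."""
    if name == "tree":
        return SklearnBackend("tree", DecisionTreeClassifier(random_state=seed))
    if name == "forest":
        return SklearnBackend("forest", RandomForestClassifier(random_state=seed))
    if name == "mlp":
        return SklearnBackend("mlp", MLPClassifier(random_state=seed))
    if name == "constant":
        return ConstantBackend()
    raise ParameterError(f"unknown backend {name!r}; choose tree/forest/mlp/constant")


# -- repeated cross-validation --------------------------------------------


@dataclass
class CVResult:
    """All repeat AUCs of a repeated-CV run plus reproducibility metadata."""

    backend: str
    repeat_aucs: list
    grand_mean_auc: float
    folds: int
    repeats: int
    seed: int
    negative_seeds: list
    feature_subset: str = "all"
    strict_cv: bool = False
    pooled: bool = False
    info_gain: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "backend": self.backend,
            "repeat_aucs": self.repeat_aucs,
            "grand_mean_auc": self.grand_mean_auc,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "negative_seeds": self.negative_seeds,
            "feature_subset": self.feature_subset,
            "strict_cv": self.strict_cv,
            "pooled": self.pooled,
            "info_gain": self.info_gain,
            "config": self.config,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _child_seeds(seed: int, n: int) -> list:
    """n reproducible sub-seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def _fold_auc(matrix, feats, backend_spec, backend_seed, train_idx, test_idx, pooled_scores):
    if callable(backend_spec):
        backend = backend_spec(backend_seed)
    else:
        backend = make_backend(backend_spec, seed=backend_seed)
    y = (matrix["label"] == LABEL_POSITIVE).astype(int).to_numpy()
    backend.fit(matrix.iloc[train_idx][feats], y[train_idx])
    scores = backend.score(matrix.iloc[test_idx][feats])
    if pooled_scores is not None:
        pooled_scores.append((scores, y[test_idx]))
        return None
    return compute_auc(scores, y[test_idx])


def repeated_cv(
    positives: AssociationSet,
    catalogs: Catalogs,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    backend: str = "forest",
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    feature_subset: str = "all",
    strict_cv: bool = False,
    pooled: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV with a fresh negative sample per repeat.

    ``feature_subset`` restricts the columns the classifier sees ('all',
    'adjacency' or 'module') — the method-ablation harness.  ``strict_cv``
    recomputes training/test features per fold with the test-fold positives
    removed from the known-association indices (a stricter leakage policy;
    off by default).  ``pooled`` pools fold scores into one AUC per repeat
    instead of averaging fold AUCs.

    ``backend`` is a registered backend name ('tree', 'forest', 'mlp',
    'constant') or any callable ``seed -> backend`` honoring the fit/score
    contract.
    """
    if len(positives) < folds:
        raise ParameterError(f"need at least {folds} positives for {folds}-fold CV")
    if feature_subset not in FEATURE_SETS:
        raise ParameterError(f"feature_subset must be one of {sorted(FEATURE_SETS)}")
    feats = list(FEATURE_SETS[feature_subset])

    neg_seeds = _child_seeds(seed, repeats)
    fold_seeds = _child_seeds(seed + 1, repeats)
    backend_seeds = _child_seeds(seed + 2, repeats * folds)

    cache: dict = {}
    repeat_aucs = []
    first_matrix = None
    for r in range(repeats):
        matrix = build_training_matrix(
            positives, catalogs, net, cfg, seed=neg_seeds[r],
            feature_cache=None if strict_cv else cache,
        )
        if first_matrix is None:
            first_matrix = matrix
        y = (matrix["label"] == LABEL_POSITIVE).astype(int).to_numpy()
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seeds[r])
        fold_aucs = []
        pooled_scores = [] if pooled else None
        for f, (train_idx, test_idx) in enumerate(skf.split(matrix[feats], y)):
            if strict_cv:
                test_pos = [
                    (row.drug, row.disease)
                    for row in matrix.iloc[test_idx].itertuples()
                    if row.label == LABEL_POSITIVE
                ]
                fold_known = positives.difference(test_pos)
                fold_matrix = _rescore_matrix(
                    matrix, catalogs, fold_known, net, cfg
                )
            else:
                fold_matrix = matrix
            try:
                auc = _fold_auc(
                    fold_matrix, feats, backend,
                    backend_seeds[r * folds + f], train_idx, test_idx, pooled_scores,
                )
            except Exception as exc:  # pragma: no cover - backend failures
                raise RuntimeError(
                    f"backend {backend!r} failed in repeat {r}, fold {f}: {exc}"
                ) from exc
            if auc is not None:
                fold_aucs.append(auc)
        if pooled:
            scores = np.concatenate([s for s, _ in pooled_scores])
            labels = np.concatenate([l for _, l in pooled_scores])
            repeat_aucs.append(compute_auc(scores, labels))
        else:
            repeat_aucs.append(float(np.mean(fold_aucs)))

    ig = information_gain(
        first_matrix[feats],
        (first_matrix["label"] == LABEL_POSITIVE).astype(int).to_numpy(),
        seed=seed,
    )
    return CVResult(
        backend=backend if isinstance(backend, str) else getattr(backend, "__name__", "custom"),
        repeat_aucs=[float(a) for a in repeat_aucs],
        grand_mean_auc=float(np.mean(repeat_aucs)),
        folds=folds,
        repeats=repeats,
        seed=seed,
        negative_seeds=neg_seeds,
        feature_subset=feature_subset,
        strict_cv=strict_cv,
        pooled=pooled,
        info_gain={k: float(v) for k, v in ig.items()},
        config={
            "base": cfg.base,
            "mode": cfg.mode,
            "path_types": sorted(cfg.path_types),
            "combine_weights": list(cfg.combine_weights),
        },
    )


def _rescore_matrix(matrix, catalogs, known, net, cfg):
    rows = []
    for row in matrix.itertuples():
        vec = build_feature_vector(
            row.drug, row.disease, catalogs, known, net, cfg, exclude_self=True
        )
        rows.append(vec.to_numpy())
    out = matrix.copy()
    out[list(FEATURE_NAMES)] = np.asarray(rows)
    return out


def information_gain(features: pd.DataFrame, labels, seed: int = 0) -> pd.Series:
    """Per-feature mutual information with the label, sorted descending.

    A diagnostic ranking of feature contribution; not used for selection.
    """
    mi = mutual_info_classif(
        features.to_numpy(), np.asarray(labels, dtype=int), random_state=seed
    )
    return pd.Series(mi, index=features.columns).sort_values(
        ascending=False, kind="stable"
    )


# -- prediction ------------------------------------------------------------


def fit_full(
    positives: AssociationSet,
    catalogs: Catalogs,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    backend: str = "forest",
    seed: int = 0,
    feature_subset: str = "all",
):
    """Train a backend on the full balanced matrix (for candidate prediction)."""
    matrix = build_training_matrix(positives, catalogs, net, cfg, seed=seed)
    feats = list(FEATURE_SETS[feature_subset])
    y = (matrix["label"] == LABEL_POSITIVE).astype(int).to_numpy()
    model = make_backend(backend, seed=seed)
    model.fit(matrix[feats], y)
    return model


def predict_candidates(
    model,
    candidates,
    catalogs: Catalogs,
    assoc: AssociationSet,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score candidate pairs and rank them by predicted association score.

    *candidates* is an iterable of (drug, disease) pairs, or None for the
    full catalog cross product.  Known positives are always excluded.
    Returns a DataFrame (drug, disease, score, predicted) sorted by score
    descending; predicted == 'yes' iff score >= threshold.
    """
    if candidates is None:
        candidates = (
            (d, p) for d in sorted(catalogs.drugs) for p in sorted(catalogs.diseases)
        )
    pairs = sorted({(d, p) for d, p in candidates if (d, p) not in assoc})
    if not pairs:
        return pd.DataFrame(columns=["drug", "disease", "score", "predicted"])
    feats = pd.DataFrame(
        [
            build_feature_vector(d, p, catalogs, assoc, net, cfg, exclude_self=False)
            for d, p in pairs
        ],
        index=pd.MultiIndex.from_tuples(pairs),
    )
    if model.feature_names_ is not None and tuple(feats.columns) != model.feature_names_:
        try:
            feats = feats[list(model.feature_names_)]
        except KeyError as exc:
            raise ParameterError(
                "feature schema mismatch between trained model and candidates"
            ) from exc
    scores = model.score(feats)
    out = pd.DataFrame(
        {
            "drug": [d for d, _ in pairs],
            "disease": [p for _, p in pairs],
            "score": scores,
        }
    )
    out["predicted"] = np.where(out["score"] >= threshold, "yes", "no")
    return out.sort_values(
        ["score", "drug", "disease"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
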