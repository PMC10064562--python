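"""One-vs-rest phenotype classification, cross-validation and ROC/AUC.

The three-class problem (cPKU / mPKU / MHP) is decomposed into three
binary one-vs-rest datasets.  Each case is encoded as a 14-dimensional
structure vector, a 16-dimensional network vector, or their 30-dimensional
concatenation, and a per-class classifier (random forest by default) is
fitted.  Evaluation follows the usual confusion-matrix rates,

    TPR = sensitivity = TP / (TP + FN)
    FPR = FP / (FP + TN)
    TNR = specificity = TN / (TN + FP),

with ROC curves from a threshold sweep over the scores and AUC by the
trapezoidal rule.  Multiclass predictions combine the three one-vs-rest
probabilities by normalised argmax, breaking exact ties toward the more
severe class.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np
import yaml
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier

from .cases import CaseDatabase, CaseRecord, Genotype
from .graph import HubSet, MutationNetwork, encode_genotype_graph
from .phenotype import SEVERITY_ORDER, Phenotype
from .regions import ExonMap
from .structure import EncodingScheme, encode_genotype_structure

__all__ = ["FeatureMode", "TrainingDataset", "EvalResult", "ModelBundle",
           "ALGORITHMS", "features_for_genotype", "assemble_features",
           "build_ovr_datasets", "train_model", "crossvalidate",
           "split_train_validation", "roc_and_auc", "fit_bundle",
           "predict_phenotype", "COMBINED_DIMS"]

COMBINED_DIMS = 30  # 14 structure + 16 graph


class FeatureMode(str, Enum):
    STRUCTURE = "structure"
    GRAPH = "graph"
    COMBINED = "combined"


_MODE_DIMS = {FeatureMode.STRUCTURE: 14, FeatureMode.GRAPH: 16,
              FeatureMode.COMBINED: COMBINED_DIMS}


def features_for_genotype(
    g: Genotype,
    mode: FeatureMode,
    xmap: ExonMap | None = None,
    scheme: EncodingScheme | None = None,
    net: MutationNetwork | None = None,
    hubs: HubSet | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Encode one genotype under the chosen feature mode.

    Structure mode needs an exon map (and optionally an encoding scheme);
    graph mode needs the network and hub set; combined concatenates
    structure first, then graph.
    """
    mode = FeatureMode(mode)
    parts = []
    if mode in (FeatureMode.STRUCTURE, FeatureMode.COMBINED):
        if xmap is None:
            raise ValueError("structure features require an exon map")
        parts.append(encode_genotype_structure(g, xmap, scheme))
    if mode in (FeatureMode.GRAPH, FeatureMode.COMBINED):
        if net is None or hubs is None:
            raise ValueError("graph features require a network and hub set")
        parts.append(encode_genotype_graph(g, net, hubs, strict=strict))
    vec = np.concatenate(parts)
    assert vec.shape == (_MODE_DIMS[mode],)
    return vec


def assemble_features(case: CaseRecord, mode: FeatureMode, **kwargs) -> np.ndarray:
    """Feature vector for a case record (delegates to the genotype encoder)."""
    return features_for_genotype(case.genotype, mode, **kwargs)


@dataclass
class TrainingDataset:
    """A one-vs-rest labelled feature matrix for one target class."""

    target_class: Phenotype
    features: np.ndarray  # (n_cases, n_dims)
    labels: np.ndarray    # 1 = target class, 0 = rest
    feature_mode: FeatureMode

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree on case count")
        if self.features.shape[1] != _MODE_DIMS[self.feature_mode]:
            raise ValueError(
                f"{self.feature_mode.value} features must have "
                f"{_MODE_DIMS[self.feature_mode]} columns, got {self.features.shape[1]}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def build_ovr_datasets(
    db: CaseDatabase,
    mode: FeatureMode,
    xmap: ExonMap | None = None,
    scheme: EncodingScheme | None = None,
    net: MutationNetwork | None = None,
    hubs: HubSet | None = None,
) -> dict[Phenotype, TrainingDataset]:
    """Build the three one-vs-rest training datasets from a cohort.

    For each phenotype class the positives are that class's cases and the
    negatives are everyone else, so ``n_positive + n_negative`` always
    equals the cohort size.
    """
    mode = FeatureMode(mode)
    counts = db.class_counts()
    empty = [p.value for p in Phenotype if counts[p] == 0]
    if empty:
        raise ValueError(f"classes with zero cases: {empty}")
    X = np.vstack([
        assemble_features(rec, mode, xmap=xmap, scheme=scheme, net=net, hubs=hubs)
        for rec in db.records
    ])
    phenotypes = np.array([rec.phenotype for rec in db.records], dtype=object)
    return {
        target: TrainingDataset(
            target_class=target,
            features=X,
            labels=(phenotypes == target).astype(int),
            feature_mode=mode,
        )
        for target in Phenotype
    }


# ---------------------------------------------------------------------------
# classifiers

def _make_classifier(algorithm: str, seed: int):
    factories = {
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=500, max_depth=None, random_state=seed, n_jobs=1),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "bernoulli_nb": lambda: BernoulliNB(),
        "k_neighbors": lambda: KNeighborsClassifier(),
    }
    if algorithm not in factories:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; supported: {sorted(factories)}"
        )
    return factories[algorithm]()


ALGORITHMS = ("random_forest", "adaboost", "gradient_boosting",
              "bernoulli_nb", "k_neighbors")


def train_model(ds: TrainingDataset, algorithm: str = "random_forest",
                seed: int = 0):
    """Fit one binary classifier on a one-vs-rest dataset (reproducible)."""
    clf = _make_classifier(algorithm, seed)
    clf.fit(ds.features, ds.labels)
    return clf


def _positive_scores(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos_col = list(clf.classes_).index(1)
    return proba[:, pos_col]


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class EvalResult:
    """ROC points, AUC and the operating point of one evaluation."""

    roc_points: np.ndarray                 # (n, 2) columns FPR, TPR
    auc: float
    sensitivity: float                     # TPR at the Youden-optimal threshold
    specificity: float                     # TNR at the same threshold
    per_fold_aucs: list[float] | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> EvalResult:
    """ROC curve by threshold sweep and AUC by the trapezoidal rule.

    The operating point reported is the threshold maximising Youden's J
    (TPR − FPR).  Requires at least one positive and one negative label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("ROC needs both classes present in the labels")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    j = int(np.argmax(tpr - fpr))
    return EvalResult(
        roc_points=np.column_stack([fpr, tpr]),
        auc=area,
        sensitivity=float(tpr[j]),
        specificity=float(1.0 - fpr[j]),
        scores=scores,
        labels=labels,
    )


def crossvalidate(ds: TrainingDataset, k: int = 10,
                  algorithm: str = "random_forest", seed: int = 0) -> EvalResult:
    """Stratified k-fold cross-validation with pooled out-of-fold scores.

    Out-of-fold scores from all folds are pooled into a single ROC/AUC;
    per-fold AUCs are retained so a fold-averaged reading is available
    too.  Each class must have at least ``k`` members.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n_pos, n_neg = ds.n_positive, ds.n_negative
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"smallest class has {min(n_pos, n_neg)} cases < k={k}; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled = np.empty(len(ds.labels), dtype=float)
    per_fold = []
    for train_idx, test_idx in skf.split(ds.features, ds.labels):
        clf = _make_classifier(algorithm, seed)
        clf.fit(ds.features[train_idx], ds.labels[train_idx])
        fold_scores = _positive_scores(clf, ds.features[test_idx])
        pooled[test_idx] = fold_scores
        per_fold.append(roc_and_auc(fold_scores, ds.labels[test_idx]).auc)
    result = roc_and_auc(pooled, ds.labels)
    result.per_fold_aucs = per_fold
    return result


def split_train_validation(ds: TrainingDataset, fraction: float = 0.8,
                           seed: int = 0) -> tuple[TrainingDataset, TrainingDataset]:
    """Stratified split into a training part and an independent hold-out."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    idx = np.arange(len(ds.labels))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=ds.labels, random_state=seed)
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("degenerate split: one side is empty")
    make = lambda sel: TrainingDataset(
        target_class=ds.target_class, features=ds.features[sel],
        labels=ds.labels[sel], feature_mode=ds.feature_mode)
    return make(np.sort(train_idx)), make(np.sort(test_idx))


# ---------------------------------------------------------------------------
# the fitted bundle and multiclass prediction

@dataclass
class ModelBundle:
    """Everything needed to reproduce predictions: the three fitted
    one-vs-rest models plus the encoding context they were trained with."""

    models: dict[Phenotype, object]
    feature_mode: FeatureMode
    xmap: ExonMap
    scheme: EncodingScheme
    net: MutationNetwork
    hubs: HubSet
    db: CaseDatabase
    algorithm: str
    seed: int
    fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.fingerprint:
            h = hashlib.sha256()
            h.update(yaml.safe_dump({
                "mode": self.feature_mode.value,
                "algorithm": self.algorithm,
                "seed": self.seed,
                "position_scale": self.scheme.position_scale,
                "n_cases": len(self.db),
            }, sort_keys=True).encode())
            self.fingerprint = h.hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} is not a model bundle")
        return bundle


def fit_bundle(db: CaseDatabase, mode: FeatureMode, xmap: ExonMap,
               scheme: EncodingScheme, net: MutationNetwork, hubs: HubSet,
               algorithm: str = "random_forest", seed: int = 0) -> ModelBundle:
    """Train all three one-vs-rest models and wrap them with their context."""
    datasets = build_ovr_datasets(db, mode, xmap=xmap, scheme=scheme,
                                  net=net, hubs=hubs)
    models = {target: train_model(ds, algorithm=algorithm, seed=seed)
              for target, ds in datasets.items()}
    return ModelBundle(models=models, feature_mode=FeatureMode(mode),
                       xmap=xmap, scheme=scheme, net=net, hubs=hubs, db=db,
                       algorithm=algorithm, seed=seed)


def predict_phenotype(g: Genotype, bundle: ModelBundle,
                      strict: bool = True) -> tuple[Phenotype, dict[Phenotype, float]]:
    """Predict a genotype's phenotype from the three one-vs-rest models.

    The three positive-class probabilities are normalised to sum to 1;
    the label is the argmax, with exact ties resolved toward the more
    severe class (cPKU > mPKU > MHP).  In strict mode a mutation absent
    from the training network raises; lenient mode substitutes
    disconnection sentinels.
    """
    x = features_for_genotype(
        g, bundle.feature_mode, xmap=bundle.xmap, scheme=bundle.scheme,
        net=bundle.net, hubs=bundle.hubs, strict=strict,
    ).reshape(1, -1)
    raw = np.array([
        _positive_scores(bundle.models[p], x)[0] for p in SEVERITY_ORDER
    ])
    total = raw.sum()
    probs = raw / total if total > 0 else np.full(len(raw), 1.0 / len(raw))
    best = SEVERITY_ORDER[0]
    for p, q in zip(SEVERITY_ORDER, probs):
        if q > probs[SEVERITY_ORDER.index(best)]:
            best = p
    return best, {p: float(q) for p, q in zip(SEVERITY_ORDER, probs)}
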