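"""Feature selection, leave-one-out classifier evaluation, and the H-score.

The modelling procedure is the one used for the clinical cohort: starting
from the per-trial feature matrix with a binary label per dog (H =
clinically treated for excessive ADHD-like behavior, C = healthy control,
first visits only), four feature-selection methods each propose a subset;
nine classifier families are evaluated on every subset with leave-one-out
cross-validation (LOOCV); precision, recall and F1 are computed from the
pooled confusion counts and ROC AUC from the pooled out-of-fold
probabilities.  The H-score of a trial is the model's predicted
probability of the H class — out-of-fold for dogs in the training cohort,
full-model for follow-up visits (which are never trained on).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, RFE, chi2 as sk_chi2, f_classif
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import BernoulliNB, ComplementNB, GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

__all__ = [
    "LabeledDataset",
    "ConfusionCounts",
    "ModelEvaluation",
    "HScoreRecord",
    "ModelSpec",
    "CLASSIFIER_IDS",
    "SELECTION_METHODS",
    "select_features",
    "loocv_evaluate",
    "compute_metrics",
    "grid_search",
    "fit_full_model",
    "h_score",
    "h_scores_out_of_fold",
]

POSITIVE_LABEL = "H"
NEGATIVE_LABEL = "C"

SELECTION_METHODS = ("f_classif", "chi2", "importance", "rfe")

CLASSIFIER_IDS = (
    "sgd", "random_forest", "knn", "gaussian_process", "gaussian_nb",
    "multinomial_nb", "bernoulli_nb", "complement_nb", "svm",
)


@dataclass
class LabeledDataset:
    """First-visit feature rows with an H/C label per dog.

    One row per dog; follow-up visits are deliberately excluded here (they
    are scored by a trained model, never trained on).
    """

    X: pd.DataFrame            # rows indexed by dog id, columns = feature ids
    y: pd.Series               # 'H' / 'C' per row, same index

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y must share the same dog-id index")
        bad = set(self.y.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"labels must be 'H' or 'C'; got {bad}")
        if self.X.index.has_duplicates:
            raise ValueError("one row per dog required")

    @property
    def feature_ids(self) -> list:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled LOOCV confusion counts; positive class = hyperactive (H)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ModelEvaluation:
    """LOOCV result of one (classifier, feature subset) combination."""

    classifier_id: str
    subset_id: str
    feature_subset: tuple
    confusion: ConfusionCounts
    precision: float
    recall: float
    f1: float
    roc_auc: float
    oof_probabilities: pd.Series   # out-of-fold P(H) per dog id
    oof_labels: pd.Series          # predicted label per dog id


@dataclass(frozen=True)
class HScoreRecord:
    dog_id: str
    visit: str                     # 'first' | 'follow-up'
    h_score: float
    provenance: str                # 'out-of-fold' | 'full-model'

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_score <= 1.0:
            raise ValueError("h_score must lie in [0, 1]")


def _impute_median(X: pd.DataFrame) -> pd.DataFrame:
    med = X.median()
    return X.fillna(med.fillna(0.0))


def select_features(data: LabeledDataset, method: str, k: int = 5,
                    seed: int = 0) -> tuple:
    """Select k features by one of four methods; deterministic given seed.

    ``f_classif``: univariate ANOVA F (constant features excluded with a
    warning); ``chi2``: chi-squared on min-max-scaled features (the test
    requires non-negative input); ``importance``: impurity importance of a
    500-tree random forest; ``rfe``: recursive feature elimination wrapped
    around the same forest, one feature per step.
    """
    if method not in SELECTION_METHODS:
        raise ValueError(f"unknown method {method!r}; use one of {SELECTION_METHODS}")
    if k > len(data.feature_ids):
        raise ValueError(f"k={k} exceeds the {len(data.feature_ids)} features")
    X = _impute_median(data.X)
    y = (data.y == POSITIVE_LABEL).astype(int).to_numpy()
    cols = np.array(X.columns)

    if method == "f_classif":
        variable = X.std(ddof=0) > 0
        if not variable.all():
            warnings.warn(f"excluding constant features under f_classif: "
                          f"{list(cols[~variable.to_numpy()])}", stacklevel=2)
        X = X.loc[:, variable]
        cols = np.array(X.columns)
        if k > X.shape[1]:
            raise ValueError("k exceeds the non-constant features")
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = SelectKBest(f_classif, k=k).fit(X, y).scores_
        order = np.argsort(-np.nan_to_num(scores))
    elif method == "chi2":
        Xs = MinMaxScaler().fit_transform(X)
        scores = SelectKBest(sk_chi2, k=k).fit(Xs, y).scores_
        order = np.argsort(-np.nan_to_num(scores))
    elif method == "importance":
        forest = RandomForestClassifier(n_estimators=500, random_state=seed)
        forest.fit(X, y)
        order = np.argsort(-forest.feature_importances_)
    else:  # rfe
        forest = RandomForestClassifier(n_estimators=500, random_state=seed)
        rfe = RFE(forest, n_features_to_select=k, step=1).fit(X, y)
        ranked = np.argsort(rfe.ranking_, kind="stable")
        return tuple(cols[ranked[:k]])
    return tuple(cols[order[:k]])


def _make_classifier(classifier_id: str, seed: int, n_train: int | None = None):
    # library defaults throughout; k-NN's k is capped by the training-fold
    # size so leave-one-out stays well defined on very small cohorts
    knn_k = 5 if n_train is None else max(1, min(5, n_train))
    builders = {
        "sgd": lambda: SGDClassifier(loss="log_loss", random_state=seed),
        "random_forest": lambda: RandomForestClassifier(random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=knn_k),
        "gaussian_process": lambda: GaussianProcessClassifier(random_state=seed),
        "gaussian_nb": lambda: GaussianNB(),
        "multinomial_nb": lambda: MultinomialNB(),
        "bernoulli_nb": lambda: BernoulliNB(),
        "complement_nb": lambda: ComplementNB(),
        "svm": lambda: SVC(probability=True, random_state=seed),
    }
    if classifier_id not in builders:
        raise ValueError(f"unknown classifier {classifier_id!r}")
    return builders[classifier_id]()


def _make_pipeline(classifier_id: str, seed: int,
                   n_train: int | None = None) -> Pipeline:
    # median imputation (fit on the training fold only) and a [0,1] rescale;
    # the multinomial/complement NB families require non-negative input
    return Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", MinMaxScaler()),
        ("clf", _make_classifier(classifier_id, seed, n_train)),
    ])


def compute_metrics(confusion: ConfusionCounts) -> tuple:
    """Precision TP/(TP+FP), recall TP/(TP+FN), F1 = 2PR/(P+R).

    Each ratio is defined as 0 (with a warning) when its denominator is 0.
    """
    if confusion.tp + confusion.fp > 0:
        p = confusion.tp / (confusion.tp + confusion.fp)
    else:
        warnings.warn("no positive predictions; precision set to 0", stacklevel=2)
        p = 0.0
    if confusion.tp + confusion.fn > 0:
        r = confusion.tp / (confusion.tp + confusion.fn)
    else:
        warnings.warn("no positive truths; recall set to 0", stacklevel=2)
        r = 0.0
    if p + r > 0:
        f1 = 2.0 * p * r / (p + r)
    else:
        warnings.warn("P + R = 0; F1 set to 0", stacklevel=2)
        f1 = 0.0
    return p, r, f1


def loocv_evaluate(data: LabeledDataset, classifier_id: str,
                   feature_subset, subset_id: str = "custom",
                   seed: int = 0) -> ModelEvaluation:
    """Leave-one-out evaluation of one classifier on one feature subset.

    Each dog is predicted by a model trained on all other dogs; confusion
    counts are pooled, P/R/F1 computed from the pooled counts and ROC AUC
    from the pooled out-of-fold probabilities.  The predicted label is the
    0.5-thresholded probability, so metrics are always recomputable from
    the stored per-dog probabilities.
    """
    subset = list(feature_subset)
    unknown = set(subset) - set(data.feature_ids)
    if unknown:
        raise ValueError(f"unknown feature ids {unknown}")
    counts = data.y.value_counts()
    if counts.get(POSITIVE_LABEL, 0) < 2 or counts.get(NEGATIVE_LABEL, 0) < 2:
        raise ValueError("need at least 2 rows per class for LOOCV")

    X = data.X[subset]
    y = (data.y == POSITIVE_LABEL).astype(int)
    probs = pd.Series(index=X.index, dtype=float)
    for i, dog in enumerate(X.index):
        train = X.index != dog
        if y[train].nunique() < 2:
            raise ValueError(f"class absent from training fold for {dog!r}")
        pipe = _make_pipeline(classifier_id, seed, n_train=data.n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            pipe.fit(X[train], y[train])
        proba = pipe.predict_proba(X.loc[[dog]])[0]
        h_col = list(pipe.classes_).index(1)
        probs[dog] = proba[h_col]

    pred = (probs >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    confusion = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1 = compute_metrics(confusion)
    auc = float(roc_auc_score(y, probs))
    labels = pred.map({1: POSITIVE_LABEL, 0: NEGATIVE_LABEL})
    return ModelEvaluation(
        classifier_id=classifier_id, subset_id=subset_id,
        feature_subset=tuple(subset), confusion=confusion,
        precision=p, recall=r, f1=f1, roc_auc=auc,
        oof_probabilities=probs, oof_labels=labels,
    )


def grid_search(data: LabeledDataset, classifier_ids=CLASSIFIER_IDS,
                subsets: dict | None = None, k: int = 5,
                seed: int = 0) -> list:
    """Evaluate every classifier on every subset; rank by F1 then AUC.

    When no subsets are given, the four selection methods each contribute
    one subset of size k.  Ties are broken by classifier/subset id so the
    ranking is fully deterministic.
    """
    if subsets is None:
        subsets = {m: select_features(data, m, k=k, seed=seed)
                   for m in SELECTION_METHODS}
    if not subsets:
        raise ValueError("at least one feature subset required")
    evals = [
        loocv_evaluate(data, clf, cols, subset_id=name, seed=seed)
        for name, cols in subsets.items()
        for clf in classifier_ids
    ]
    evals.sort(key=lambda e: (-e.f1, -e.roc_auc, e.classifier_id, e.subset_id))
    return evals


@dataclass
class ModelSpec:
    """Exportable description of the winning scoring model."""

    classifier_id: str
    subset_id: str
    feature_subset: tuple
    seed: int
    imputation_medians: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["feature_subset"] = tuple(d["feature_subset"])
        return cls(**d)


def fit_full_model(data: LabeledDataset, spec: ModelSpec):
    """Fit the spec'd pipeline on the whole first-visit cohort."""
    if data.y.nunique() < 2:
        raise ValueError("cannot fit a scoring model on a single class")
    X = data.X[list(spec.feature_subset)]
    y = (data.y == POSITIVE_LABEL).astype(int)
    pipe = _make_pipeline(spec.classifier_id, spec.seed, n_train=data.n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        pipe.fit(X, y)
    spec.imputation_medians = {c: float(m) for c, m in
                               zip(spec.feature_subset, X.median().fillna(0.0))}
    return pipe


def h_score(model, spec: ModelSpec, features: dict | pd.Series,
            dog_id: str = "", visit: str = "follow-up") -> HScoreRecord:
    """Score one trial with a fitted full model: P(H class).

    Used for follow-up visits and for any trial outside the training
    cohort.  Missing values are imputed with the training medians (with a
    warning); unseen feature ids are an error.
    """
    row = pd.Series(features, dtype=float)
    missing_ids = set(spec.feature_subset) - set(row.index)
    if missing_ids:
        raise ValueError(f"feature vector lacks required ids {missing_ids}")
    row = row[list(spec.feature_subset)]
    if row.isna().any():
        warnings.warn(f"imputing missing features for {dog_id!r} with training "
                      "medians", stacklevel=2)
        med = pd.Series(spec.imputation_medians)
        row = row.fillna(med)
    proba = model.predict_proba(row.to_frame().T.set_axis(
        list(spec.feature_subset), axis=1))[0]
    h_col = list(model.classes_).index(1)
    return HScoreRecord(dog_id=dog_id, visit=visit,
                        h_score=float(proba[h_col]), provenance="full-model")


def h_scores_out_of_fold(evaluation: ModelEvaluation) -> list:
    """H-scores of the training cohort: the leakage-free out-of-fold P(H)."""
    return [HScoreRecord(dog_id=str(dog), visit="first",
                         h_score=float(p), provenance="out-of-fold")
            for dog, p in evaluation.oof_probabilities.items()]
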