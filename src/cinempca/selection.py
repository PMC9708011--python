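"""Feature ranking, stepwise selection, and SVM mortality classification.

MPCA features are ranked by Fisher's discriminant ratio, a feature count is
chosen by stepwise inclusion against a random held-out tuning set (~50
cases), and a linear-kernel SVM with Platt-style probability calibration is
trained on the winners.  Model development runs under repeated stratified
cross-validation (10 rounds of 10 folds by default) with MPCA refit, ranking
and selection restricted to each fold's training portion so no information
leaks from the evaluation folds.  A dual-scan model concatenates the selected
short-axis and four-chamber feature blocks and trains one further SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .mpca import MPCAModel, fit_mpca, project_batch

FISHER_EPS = 1e-12


@dataclass
class SelectedFeatureSet:
    """Ordered feature indices surviving Fisher ranking + stepwise inclusion."""

    indices: np.ndarray  # into the (variance-ordered) feature vector
    fisher_scores: np.ndarray  # aligned with indices, non-increasing
    tuning_metric: float  # AUC on the tuning set


@dataclass
class TrainedPrognosticModel:
    view: str  # "SA", "4Ch" or "combined"
    selected: SelectedFeatureSet
    weight_vector: np.ndarray
    bias: float
    calibration_slope: float
    calibration_intercept: float
    #: signed class-mean difference per selected feature on the training set
    #: (mortality minus survival); drives the contrast saliency weighting
    feature_contrast: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def decision_values(self, features):
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] == len(self.selected.indices):
            sub = X
        else:
            sub = X[:, self.selected.indices]
        return sub @ self.weight_vector + self.bias


@dataclass
class CVReport:
    rounds: int
    folds: int
    fold_aucs: np.ndarray  # rounds*folds entries
    fold_set_sizes: np.ndarray
    fold_selected: list  # per fold: canonical core indices of the selection
    best_fold: int
    chosen_canonical_indices: np.ndarray
    seed: int

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.fold_aucs, 12).tobytes())
        h.update(self.fold_set_sizes.astype(np.int64).tobytes())
        h.update(self.chosen_canonical_indices.astype(np.int64).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Fisher ranking
# ---------------------------------------------------------------------------

def fisher_score(feature_column, labels) -> float:
    """Fisher's discriminant ratio (mu1 - mu0)^2 / (var1 + var0).

    Population variances; a tiny epsilon guards the zero-variance case.
    Scale-invariant and nonnegative.
    """
    x = np.asarray(feature_column, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    x0, x1 = x[~y], x[y]
    num = (x1.mean() - x0.mean()) ** 2
    den = x1.var(ddof=0) + x0.var(ddof=0)
    return float(num / (den + FISHER_EPS))


def fisher_scores(features, labels) -> np.ndarray:
    """Vectorized Fisher ratio per column."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    m0, m1 = X[~y].mean(axis=0), X[y].mean(axis=0)
    v0, v1 = X[~y].var(axis=0, ddof=0), X[y].var(axis=0, ddof=0)
    return (m1 - m0) ** 2 / (v0 + v1 + FISHER_EPS)


# ---------------------------------------------------------------------------
# SVM + calibration
# ---------------------------------------------------------------------------

def _fit_linear_svm(X, y, C=1.0):
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf


def train_svm(
    features, labels, C: float = 1.0, seed: int = 0, calibrate: bool = True
) -> TrainedPrognosticModel:
    """Linear-kernel maximum-margin classifier with Platt-style calibration.

    Calibration fits a logistic map on decision values collected from an
    internal stratified cross-validation, so the probability scale is not
    tuned on the same margins it is applied to.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.ndim != 2:
        raise ValueError("features must be 2-D (cases x features)")
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 cases per class")
    for cls in (False, True):
        rows = X[y == cls]
        if len(rows) > 1 and np.allclose(rows, rows[0]):
            other = X[y != cls]
            if any(np.allclose(rows[0], r) for r in other):
                raise ValueError("identical feature rows across classes: inseparable input")
    clf = _fit_linear_svm(X, y, C=C)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])

    slope, intercept = 1.0, 0.0
    if calibrate:
        n_splits = int(min(5, y.sum(), (~y).sum()))
        dec = np.empty(len(y))
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for tr, te in skf.split(X, y):
                fold_clf = _fit_linear_svm(X[tr], y[tr], C=C)
                dec[te] = fold_clf.decision_function(X[te])
        else:
            dec = clf.decision_function(X)
        lr = LogisticRegression(C=1e6)
        lr.fit(dec[:, None], y)
        slope = float(lr.coef_[0, 0])
        intercept = float(lr.intercept_[0])
        if slope < 0:
            # cross-validated margins can anti-correlate with labels on null
            # data; the probability map must stay monotone in the decision
            # value, so fall back to in-sample margins (which separate the
            # training labels in the positive direction by construction)
            lr.fit(clf.decision_function(X)[:, None], y)
            slope = float(lr.coef_[0, 0])
            intercept = float(lr.intercept_[0])

    sel = SelectedFeatureSet(
        indices=np.arange(X.shape[1]),
        fisher_scores=fisher_scores(X, y),
        tuning_metric=float("nan"),
    )
    return TrainedPrognosticModel(
        view="unspecified", selected=sel, weight_vector=w, bias=b,
        calibration_slope=slope, calibration_intercept=intercept,
        feature_contrast=X[y].mean(axis=0) - X[~y].mean(axis=0),
        provenance={"C": C, "seed": seed, "n_train": int(len(y))},
    )


def predict_probability(model: TrainedPrognosticModel, features) -> np.ndarray:
    """Calibrated mortality probability, monotone in the SVM decision value."""
    X = np.asarray(features, dtype=float)
    squeeze = X.ndim == 1
    dec = model.decision_values(X)
    p = 1.0 / (1.0 + np.exp(-(model.calibration_slope * dec + model.calibration_intercept)))
    return float(p[0]) if squeeze else p


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(
    features,
    labels,
    tuning_size: int = 50,
    max_k: int = 30,
    seed: int = 0,
    C: float = 1.0,
) -> SelectedFeatureSet:
    """Fisher-rank features, then grow the model one feature at a time.

    A random stratified tuning set (default ~50 cases) is held out; for each
    k in 1..max_k an SVM trained on the remaining cases with the top-k
    features is scored by AUC on the tuning set, and the best k wins (ties
    resolved toward the smaller model).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(y)
    tuning_size = min(tuning_size, n // 2)
    if tuning_size < 2:
        raise ValueError("not enough cases for a tuning split")

    def draw():
        pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
        n_pos = max(1, int(round(tuning_size * y.mean())))
        n_pos = min(n_pos, len(pos) - 1)
        n_neg = min(tuning_size - n_pos, len(neg) - 1)
        idx = np.concatenate([
            rng.choice(pos, size=n_pos, replace=False),
            rng.choice(neg, size=n_neg, replace=False),
        ])
        return np.sort(idx)

    tune_idx = draw()
    if y[tune_idx].all() or not y[tune_idx].any():
        tune_idx = draw()
        if y[tune_idx].all() or not y[tune_idx].any():
            raise ValueError("tuning set missing a class after resampling")
    train_mask = np.ones(n, dtype=bool)
    train_mask[tune_idx] = False
    Xtr, ytr = X[train_mask], y[train_mask]
    Xtu, ytu = X[tune_idx], y[tune_idx]
    if ytr.sum() < 2 or (~ytr).sum() < 2:
        raise ValueError("training portion lacks class representation")

    scores = fisher_scores(Xtr, ytr)
    ranking = np.argsort(-scores, kind="stable")
    max_k = min(max_k, X.shape[1])

    best_k, best_auc = 1, -np.inf
    for k in range(1, max_k + 1):
        cols = ranking[:k]
        clf = _fit_linear_svm(Xtr[:, cols], ytr, C=C)
        auc = roc_auc_score(ytu, clf.decision_function(Xtu[:, cols]))
        if auc > best_auc + 1e-12:
            best_auc, best_k = auc, k
    chosen = ranking[:best_k]
    return SelectedFeatureSet(
        indices=chosen, fisher_scores=scores[chosen], tuning_metric=float(best_auc)
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fit_fold_model(tensors_or_features, labels, mpca_kwargs, select_kwargs, mpca_model=None):
    """Fit MPCA (if raw tensors given) + selection on one training set."""
    if mpca_model is None and tensors_or_features.ndim == 4:
        mpca_model = fit_mpca(tensors_or_features, **mpca_kwargs)
    if mpca_model is not None:
        feats = project_batch(mpca_model, tensors_or_features)
    else:
        feats = tensors_or_features
    sel = stepwise_select(feats, labels, **select_kwargs)
    return mpca_model, feats, sel


def cross_validate(
    tensors,
    labels,
    rounds: int = 10,
    folds: int = 10,
    seed: int = 0,
    variance_kept: float = 0.97,
    tuning_size: int = 50,
    max_k: int = 30,
    C: float = 1.0,
    refit_mpca_per_fold: bool = True,
    best_by: str = "single_fold",
    provenance_log: list | None = None,
    subject_ids=None,
):
    """Repeated stratified k-fold development loop.

    Per fold: MPCA fit + Fisher ranking + stepwise selection on the training
    portion only; AUC measured on the left-out fold.  The canonical core
    indices of the selection achieving the best fold AUC (or best
    round-average with ``best_by='round_mean'``) are refit on the full
    development set to produce the final model.

    Returns ``(CVReport, TrainedPrognosticModel, MPCAModel)``.
    """
    batch = np.stack([np.asarray(t, dtype=float) for t in tensors], axis=0)
    y = np.asarray(labels, dtype=bool)
    n = len(y)
    if n < folds:
        raise ValueError("need at least `folds` cases")
    min_class = int(min(y.sum(), (~y).sum()))
    if min_class < folds:
        folds = max(2, min_class)
    rng = np.random.default_rng(seed)

    shared_mpca = None
    if not refit_mpca_per_fold:
        shared_mpca = fit_mpca(batch, variance_kept=variance_kept)

    fold_aucs, fold_sizes, fold_selected = [], [], []
    fold_id = 0
    for rnd in range(rounds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for tr, te in skf.split(np.zeros(n), y):
            if provenance_log is not None and subject_ids is not None:
                provenance_log.append(
                    {"stage": "cv_fold_fit", "fold": fold_id,
                     "subject_ids": [subject_ids[i] for i in tr]}
                )
            mpca_model, feats_tr, sel = _fit_fold_model(
                batch[tr], y[tr],
                {"variance_kept": variance_kept},
                {"tuning_size": tuning_size, "max_k": max_k,
                 "seed": int(rng.integers(2**31 - 1)), "C": C},
                mpca_model=shared_mpca,
            )
            clf = _fit_linear_svm(feats_tr[:, sel.indices], y[tr], C=C)
            feats_te = project_batch(mpca_model, batch[te])
            auc = roc_auc_score(y[te], clf.decision_function(feats_te[:, sel.indices]))
            fold_aucs.append(float(auc))
            fold_sizes.append(len(sel.indices))
            # store selections as (row, col, frame) core triples: the retained
            # core shape can differ between folds, so flat indices don't carry
            flat = mpca_model.canonical_index(sel.indices)
            fold_selected.append(np.stack(
                np.unravel_index(flat, mpca_model.core_shape), axis=1))
            fold_id += 1

    fold_aucs = np.asarray(fold_aucs)
    if best_by == "round_mean":
        means = fold_aucs.reshape(rounds, -1).mean(axis=1)
        best_round = int(np.argmax(means))
        within = fold_aucs.reshape(rounds, -1)[best_round]
        best = best_round * (len(fold_aucs) // rounds) + int(np.argmax(within))
    else:
        best = int(np.argmax(fold_aucs))
    chosen_triples = np.asarray(fold_selected[best])

    # refit on the full development set
    if provenance_log is not None and subject_ids is not None:
        provenance_log.append({"stage": "final_fit", "subject_ids": list(subject_ids)})
    final_mpca = shared_mpca if shared_mpca is not None else fit_mpca(
        batch, variance_kept=variance_kept
    )
    feats = project_batch(final_mpca, batch, ordered=False)
    # carry the winning core triples into the refit core, dropping any that
    # fall outside the (possibly smaller) retained dimensions
    core_shape = final_mpca.core_shape
    in_range = np.all(chosen_triples < np.asarray(core_shape), axis=1)
    kept = chosen_triples[in_range]
    if kept.size == 0:
        valid = np.argsort(-fisher_scores(feats, y), kind="stable")[:1]
    else:
        valid = np.ravel_multi_index(tuple(kept.T), core_shape)
    model = train_svm(feats[:, valid], y, C=C, seed=seed)
    model.view = "development"
    model.selected = SelectedFeatureSet(
        indices=valid,
        fisher_scores=fisher_scores(feats, y)[valid],
        tuning_metric=float(fold_aucs[best]),
    )
    model.provenance.update({
        "rounds": rounds, "folds": folds, "seed": seed,
        "variance_kept": variance_kept, "canonical_indices": valid.tolist(),
        "feature_space": "canonical_core",
    })
    report = CVReport(
        rounds=rounds, folds=folds, fold_aucs=fold_aucs,
        fold_set_sizes=np.asarray(fold_sizes), fold_selected=fold_selected,
        best_fold=best, chosen_canonical_indices=valid, seed=seed,
    )
    return report, model, final_mpca


def score_studies(model: TrainedPrognosticModel, mpca_model: MPCAModel, tensors):
    """Mortality probabilities for new tensors under a development model that
    stores canonical core indices."""
    feats = project_batch(mpca_model, tensors, ordered=False)
    return predict_probability(model, feats[:, model.selected.indices])


# ---------------------------------------------------------------------------
# dual-view fusion
# ---------------------------------------------------------------------------

def combine_dual_scan(
    sa_features, fourch_features, labels, C: float = 1.0, seed: int = 0
) -> TrainedPrognosticModel:
    """Train the dual-scan SVM on concatenated selected-feature blocks.

    Inputs are each view's already-selected feature columns for the same
    subjects, in the same subject order.
    """
    A = np.asarray(sa_features, dtype=float)
    B = np.asarray(fourch_features, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("views must cover the same subjects in the same order")
    X = np.concatenate([A, B], axis=1)
    model = train_svm(X, labels, C=C, seed=seed)
    model.view = "combined"
    model.provenance["block_sizes"] = (A.shape[1], B.shape[1])
    return model
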