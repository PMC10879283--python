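"""Stratified 10-fold nested cross-validation with inner-fold ensembling.

Each outer fold holds out ~10% of subjects as an independent test set.
The remaining 90% is partitioned by a stratified 9-fold split whose nine
rotations provide nine (train ~80%, validation ~10%) inner splits; one
network is trained per rotation and the outer-fold prediction is the
*probabilistic ensemble* — the arithmetic mean of the nine members'
softmax outputs, argmax decoded with ties broken toward the lowest
class index.

Harmonization is refit per outer fold on the non-test 90% only and
applied to all rows with those frozen coefficients, so no test-subject
information reaches either the harmonizer or the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .atlas import N_CORTICAL
from .classifier import ParallelEmbeddingClassifier
from .harmonize import WScoreHarmonizer
from .metrics import confusion, metrics_report, overall_balanced_accuracy
from .tables import DIAGNOSES, FeatureTable

N_INNER = 9

#: feature views used by the ablation study -> (column slice, architecture)
FEATURE_VIEWS = {
    "all": slice(0, 735),
    "thickness": slice(0, N_CORTICAL),
    "volume": slice(N_CORTICAL, 735),
}


class SplitError(ValueError):
    """Labels cannot support the requested stratified split."""


@dataclass
class OuterFold:
    test_idx: np.ndarray
    inner_splits: list[tuple[np.ndarray, np.ndarray]]  # (train, val) absolute idx


@dataclass
class NestedSplit:
    """k outer folds, each with 9 inner train/validation rotations."""

    folds: list[OuterFold]
    k: int
    seed: int


def make_nested_splits(labels, k: int = 10, seed: int = 0) -> NestedSplit:
    """Build the stratified nested split (deterministic given seed)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise SplitError(
            f"class {small!r} has {counts.min()} subjects, fewer than k={k}"
        )
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    idx = np.arange(len(labels))
    for f, (trainval, test) in enumerate(outer.split(idx, labels)):
        inner = StratifiedKFold(
            n_splits=N_INNER, shuffle=True, random_state=seed + 1000 + f
        )
        inner_splits = [
            (trainval[tr], trainval[va])
            for tr, va in inner.split(trainval, labels[trainval])
        ]
        folds.append(OuterFold(test_idx=test, inner_splits=inner_splits))
    return NestedSplit(folds=folds, k=k, seed=seed)


@dataclass
class TrainedEnsemble:
    """The nine inner-fold models of one outer fold + their harmonizer."""

    members: list[ParallelEmbeddingClassifier]
    harmonizer: WScoreHarmonizer | None
    fold_index: int

    def __post_init__(self) -> None:
        if len(self.members) != N_INNER:
            raise ValueError(
                f"ensemble needs exactly {N_INNER} members, got {len(self.members)}"
            )


def ensemble_predict(
    ensemble: TrainedEnsemble, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean softmax over the nine members; argmax labels (lowest-index ties).

    ``X`` must already be harmonized with the ensemble's harmonizer.
    Returns (probabilities of shape (n, 3), predicted labels).
    """
    proba = np.mean([m.predict_proba(X) for m in ensemble.members], axis=0)
    labels = ensemble.members[0].classes_[np.argmax(proba, axis=1)]
    return proba, labels


def train_inner_model(
    X_train, y_train, X_val, y_val, random_state: int = 0, **clf_kwargs
) -> ParallelEmbeddingClassifier:
    """Train one inner-fold network, checkpointing the best validation epoch."""
    clf = ParallelEmbeddingClassifier(random_state=random_state, **clf_kwargs)
    return clf.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def _member_seed(seed: int, fold: int, inner: int) -> int:
    return (seed * 100003 + fold * 101 + inner) % (2**31)


def fit_outer_fold(
    table: FeatureTable,
    fold: OuterFold,
    fold_index: int,
    seed: int,
    feature_view: str = "all",
    architecture: str = "parallel",
    harmonize: bool = True,
    covariates: tuple[str, ...] | None = None,
    harmonization_scope: str = "trainval",
    **clf_kwargs,
) -> tuple[TrainedEnsemble, np.ndarray]:
    """Fit one outer fold's harmonizer + nine networks.

    Returns the ensemble and the full w-score matrix (test rows included,
    transformed with training-only coefficients).
    ``harmonization_scope="all"`` deliberately fits the harmonizer on all
    rows including the test set; it exists only as the leakage audit's
    negative control and must never be used for evaluation.
    """
    y = table.diagnosis
    harmonizer = None
    if harmonize:
        trainval_idx = np.setdiff1d(
            np.arange(table.n_subjects), fold.test_idx
        )
        kwargs = {} if covariates is None else {"covariates": covariates}
        fit_table = (
            table if harmonization_scope == "all" else table.subset(trainval_idx)
        )
        harmonizer = WScoreHarmonizer(**kwargs).fit(fit_table)
        W = harmonizer.transform(table).X
    else:
        W = table.X
    cols = FEATURE_VIEWS[feature_view]
    W = W[:, cols]

    members = []
    for j, (tr, va) in enumerate(fold.inner_splits):
        members.append(
            train_inner_model(
                W[tr], y[tr], W[va], y[va],
                random_state=_member_seed(seed, fold_index, j),
                architecture=architecture,
                **clf_kwargs,
            )
        )
    return TrainedEnsemble(members, harmonizer, fold_index), W


@dataclass
class NestedCVResult:
    """Pooled and per-fold evaluation of one nested-CV run."""

    ensembles: list[TrainedEnsemble]
    y_true: np.ndarray
    y_pred: np.ndarray
    proba: np.ndarray
    report: dict
    per_fold_overall_ba: list[float]
    per_fold_reports: list[dict] = field(default_factory=list)


def run_nested_cv(
    table: FeatureTable,
    seed: int = 0,
    k: int = 10,
    feature_view: str = "all",
    architecture: str = "parallel",
    splits: NestedSplit | None = None,
    harmonize: bool = True,
    covariates: tuple[str, ...] | None = None,
    **clf_kwargs,
) -> NestedCVResult:
    """Full nested CV: per-fold harmonize, train 9 nets, ensemble, evaluate.

    Per-class balanced accuracies in ``result.report`` come from the
    confusion matrix pooled over all outer test sets; per-fold overall
    balanced accuracies are also returned for dispersion plots.
    """
    y = table.diagnosis
    if splits is None:
        splits = make_nested_splits(y, k=k, seed=seed)
    n = table.n_subjects
    y_pred = np.empty(n, dtype=object)
    proba = np.full((n, len(DIAGNOSES)), np.nan)
    ensembles, per_fold_ba, per_fold_reports = [], [], []
    for f, fold in enumerate(splits.folds):
        ensemble, W = fit_outer_fold(
            table, fold, f, seed,
            feature_view=feature_view,
            architecture=architecture,
            harmonize=harmonize,
            covariates=covariates,
            **clf_kwargs,
        )
        p, lab = ensemble_predict(ensemble, W[fold.test_idx])
        proba[fold.test_idx] = p
        y_pred[fold.test_idx] = lab
        ensembles.append(ensemble)
        rep = metrics_report(
            _encode(y[fold.test_idx]), _encode(lab)
        )
        per_fold_reports.append(rep)
        per_fold_ba.append(rep["overall_balanced_accuracy"])
    report = metrics_report(_encode(y), _encode(y_pred))
    return NestedCVResult(
        ensembles=ensembles,
        y_true=y,
        y_pred=y_pred.astype(str),
        proba=proba,
        report=report,
        per_fold_overall_ba=per_fold_ba,
        per_fold_reports=per_fold_reports,
    )


def _encode(y) -> np.ndarray:
    idx = {d: i for i, d in enumerate(DIAGNOSES)}
    return np.array([idx[v] for v in y], dtype=int)


#: the four experiments of the ablation study, in reporting order
ABLATION_EXPERIMENTS = {
    "volume": dict(feature_view="volume", architecture="single"),
    "thickness": dict(feature_view="thickness", architecture="single"),
    "concat": dict(feature_view="all", architecture="concat"),
    "parallel": dict(feature_view="all", architecture="parallel"),
}


def run_ablation(
    table: FeatureTable,
    seed: int = 0,
    k: int = 10,
    experiments: tuple[str, ...] = ("volume", "thickness", "concat", "parallel"),
    **clf_kwargs,
) -> dict[str, NestedCVResult]:
    """Run the four-way feature/architecture comparison on shared splits.

    All experiments reuse the identical outer/inner splits so that test
    sets are matched across rows of the resulting comparison table.
    """
    splits = make_nested_splits(table.diagnosis, k=k, seed=seed)
    results = {}
    for name in experiments:
        spec = ABLATION_EXPERIMENTS[name]
        results[name] = run_nested_cv(
            table, seed=seed, k=k, splits=splits, **spec, **clf_kwargs
        )
    return results


def ablation_table(results: dict[str, NestedCVResult]):
    """Per-experiment per-class + overall balanced accuracy, as a DataFrame."""
    import pandas as pd

    rows = []
    for name, res in results.items():
        row = {"experiment": name}
        row.update(res.report["per_class_balanced_accuracy"])
        row["overall"] = res.report["overall_balanced_accuracy"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("experiment")
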