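"""Random-forest species and sex predictors with out-of-bag error.

These classifiers are a data-integrity check, not a biological claim: on a
correctly plated methylation dataset, species and sex are so strongly encoded
(species baseline offsets; X-linked probes) that a forest should separate
them perfectly, so a nonzero out-of-bag (OOB) error flags plate-map or
labelling mistakes.

The forest itself is scikit-learn's; what this module owns is the OOB
protocol: every sample is scored only by trees whose bootstrap resample
excluded it, and samples that no tree left out are removed from the error
denominator rather than silently counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .datamodel import BetaMatrix, SampleRecord, ValidationError

__all__ = ["ClassifierReport", "fit_rf_classifier", "check_labels"]


@dataclass
class ClassifierReport:
    """Out-of-bag evaluation of a categorical methylation predictor."""

    target: str
    oob_error: float
    confusion: np.ndarray  # rows = true class, cols = OOB-predicted class
    classes: tuple[str, ...]
    n_trees: int
    seed: int
    n_scored: int  # samples that received at least one OOB vote
    n_unscored: int


def fit_rf_classifier(
    beta: BetaMatrix,
    labels: list[str],
    target: str = "species",
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Bootstrap-aggregated decision trees (sqrt(p) features per split) with
    OOB error.

    ``labels`` must align with ``beta.sample_ids``; needs >= 2 classes each
    with >= 2 samples.  Missing betas are not supported (the integrity check
    runs on the normalized matrix as shipped).
    """
    X = beta.values.T  # samples x probes
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("labels must align with beta matrix samples")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValidationError(f"classes with fewer than 2 samples: {small}")
    if np.isnan(X).any():
        raise ValidationError("missing beta values are not supported")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=int(seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # with very few trees some samples get no OOB vote; handled below
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        warnings.filterwarnings("ignore", message="invalid value encountered")
        rf.fit(X, y)
        votes = rf.oob_decision_function_  # (n, n_classes), rows may be all-NaN/0
    vote_mass = np.nan_to_num(votes, nan=0.0).sum(axis=1)
    scored = vote_mass > 0
    pred_idx = np.nan_to_num(votes, nan=0.0).argmax(axis=1)
    pred = rf.classes_[pred_idx]
    k = len(rf.classes_)
    class_index = {c: i for i, c in enumerate(rf.classes_)}
    confusion = np.zeros((k, k), dtype=int)
    for true_label, pred_label, ok in zip(y, pred, scored):
        if ok:
            confusion[class_index[true_label], class_index[pred_label]] += 1
    n_scored = int(scored.sum())
    mis = int(confusion.sum() - np.trace(confusion))
    oob_error = mis / n_scored if n_scored else float("nan")
    return ClassifierReport(
        target=target,
        oob_error=float(oob_error),
        confusion=confusion,
        classes=tuple(str(c) for c in rf.classes_),
        n_trees=int(n_trees),
        seed=int(seed),
        n_scored=n_scored,
        n_unscored=int((~scored).sum()),
    )


def check_labels(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    target: str = "species",
    n_trees: int = 500,
    seed: int = 0,
) -> ClassifierReport:
    """Convenience wrapper: predict species or sex from the sample sheet.

    Samples with unknown sex are excluded from the sex classifier.
    """
    if target not in ("species", "sex"):
        raise ValidationError(f"target must be species or sex, got {target!r}")
    keep = [s for s in samples if target != "sex" or s.sex in ("F", "M")]
    sub = beta.subset_samples([s.sample_id for s in keep])
    labels = [getattr(s, target) for s in keep]
    return fit_rf_classifier(sub, labels, target=target, n_trees=n_trees, seed=seed)
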