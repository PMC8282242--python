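"""Train, apply and cross-validate epigenetic clocks.

A clock is an elastic-net regression (alpha = 0.5 by default, penalty chosen
by internal 10-fold CV) of transformed chronological age on CpG beta values.
Accuracy is always reported on the years scale after inverting the transform:
Pearson correlation R between DNAm age and chronological age, and the median
absolute error (MAE) in years.

Two unbiased evaluation schemes are provided:

* ``loocv``  — leave one sample out; the entire fitting procedure (penalty
  selection included) reruns without the held-out sample, so nothing about
  that sample can leak into its own prediction.
* ``lofo10`` — 10-fold CV with folds stratified so every fold carries each
  species in (near-)exact proportion; used for multi-species clocks where a
  random fold could under-represent the smaller cohort.

Epigenetic age acceleration — the discrepancy between DNAm age and
chronological age — is computed either as the raw difference (``delta``) or
as the residual from regressing DNAm age on chronological age (``residual``).
"""

from __future__ import annotations

import numpy as np

from .datamodel import (
    AgeTransformSpec,
    BetaMatrix,
    ClockModel,
    CVReport,
    SampleRecord,
    ValidationError,
)
from .enet import cv_select_lambda, enet_path
from .transforms import inverse_transform_ages, transform_ages

__all__ = [
    "train_clock",
    "predict_age",
    "loocv",
    "lofo10",
    "stratified_folds",
    "age_acceleration",
    "acceleration_correlations",
]


def _design(
    beta: BetaMatrix, samples: list[SampleRecord], impute: bool = False
) -> np.ndarray:
    """Samples x probes design matrix for the given samples, in their order."""
    sub = beta.subset_samples([s.sample_id for s in samples])
    X = sub.values.T.copy()
    if np.isnan(X).any():
        if not impute:
            raise ValidationError(
                "beta matrix contains missing values; pass impute=True to use "
                "per-probe mean imputation"
            )
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)  # all-missing probe
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = col_mean[nan_c]
    return X


def train_clock(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    transform: AgeTransformSpec,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 10,
    impute: bool = False,
) -> ClockModel:
    """Fit a clock on all given samples; penalty by seeded internal k-fold CV.

    Only nonzero coefficients are stored in the returned model.
    """
    ages = np.array([s.age_years for s in samples], dtype=float)
    species = [s.species for s in samples]
    y = transform_ages(ages, species, transform)
    if np.ptp(y) == 0:
        raise ValidationError(
            "degenerate response: all samples have the same (transformed) age"
        )
    X = _design(beta, samples, impute=impute)
    lam_min, _ = cv_select_lambda(X, y, alpha=alpha, n_folds=n_folds, seed=seed)
    lambdas, icpts, coefs = enet_path(X, y, alpha=alpha)
    k = int(np.argmin(np.abs(lambdas - lam_min)))
    coef = coefs[k]
    nonzero = {
        beta.probe_ids[j]: float(coef[j]) for j in np.flatnonzero(coef)
    }
    return ClockModel(
        intercept=float(icpts[k]),
        coefficients=nonzero,
        alpha=float(alpha),
        lam=float(lam_min),
        transform=transform,
        training_species=tuple(sorted(set(species))),
        n_train=len(samples),
    )


def predict_age(
    model: ClockModel,
    beta: BetaMatrix,
    species_of: dict[str, str],
    impute: bool = False,
) -> np.ndarray:
    """DNAm age in years for every sample (column) of ``beta``.

    ``species_of`` maps sample_id -> species so the inverse transform can use
    the right per-species parameters.  Every model probe must be present in
    ``beta`` (missing betas tolerated only with ``impute=True``).
    """
    probe_index = {p: i for i, p in enumerate(beta.probe_ids)}
    missing = [p for p in model.coefficients if p not in probe_index]
    if missing:
        raise ValidationError(f"model probes absent from beta matrix: {missing}")
    unknown = [s for s in beta.sample_ids if s not in species_of]
    if unknown:
        raise ValidationError(f"samples without species assignment: {unknown}")
    probes = sorted(model.coefficients)
    w = np.array([model.coefficients[p] for p in probes])
    V = beta.values[[probe_index[p] for p in probes], :]  # probes x samples
    if np.isnan(V).any():
        if not impute:
            raise ValidationError("missing beta values; pass impute=True")
        row_mean = np.nanmean(V, axis=1)
        row_mean = np.where(np.isnan(row_mean), 0.5, row_mean)
        nan_r, nan_c = np.where(np.isnan(V))
        V = V.copy()
        V[nan_r, nan_c] = row_mean[nan_r]
    linpred = model.intercept + w @ V if probes else np.full(
        len(beta.sample_ids), model.intercept
    )
    linpred = np.atleast_1d(np.asarray(linpred, dtype=float))
    species = [species_of[s] for s in beta.sample_ids]
    return inverse_transform_ages(linpred, species, model.transform)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds below 2**31, reproducible from the root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _evaluate_holdouts(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    transform: AgeTransformSpec,
    alpha: float,
    fold_of: np.ndarray,
    fold_seeds: list[int],
    n_folds_inner: int,
    impute: bool,
) -> CVReport:
    """Shared CV engine: refit (with internal penalty selection) per fold and
    predict the held-out samples in years."""
    X = _design(beta, samples, impute=impute)
    ages = np.array([s.age_years for s in samples], dtype=float)
    species = [s.species for s in samples]
    y = transform_ages(ages, species, transform)
    per_sample: list[tuple[str, int, float, float]] = []
    for k in sorted(set(fold_of)):
        test = fold_of == k
        train = ~test
        lam_min, _ = cv_select_lambda(
            X[train], y[train], alpha=alpha, n_folds=n_folds_inner,
            seed=fold_seeds[k],
        )
        lambdas, icpts, coefs = enet_path(X[train], y[train], alpha=alpha)
        j = int(np.argmin(np.abs(lambdas - lam_min)))
        pred_t = X[test] @ coefs[j] + icpts[j]
        test_idx = np.flatnonzero(test)
        pred_years = inverse_transform_ages(
            pred_t, [species[i] for i in test_idx], transform
        )
        for i, py in zip(test_idx, pred_years):
            per_sample.append((samples[i].sample_id, int(k), float(ages[i]), float(py)))
    order = {s.sample_id: i for i, s in enumerate(samples)}
    per_sample.sort(key=lambda row: order[row[0]])
    return CVReport.from_per_sample(per_sample)


def loocv(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    transform: AgeTransformSpec,
    alpha: float = 0.5,
    seed: int = 0,
    impute: bool = False,
) -> CVReport:
    """Leave-one-sample-out cross-validation.

    Each sample's age is predicted by a clock trained entirely without it;
    needs n >= 11 so the internal 10-fold penalty selection fits inside every
    training split.
    """
    n = len(samples)
    if n < 11:
        raise ValidationError(f"LOOCV needs n >= 11 samples, got {n}")
    fold_of = np.arange(n)
    seeds = _spawn_seeds(seed, n)
    return _evaluate_holdouts(
        beta, samples, transform, alpha, fold_of, seeds, 10, impute
    )


def stratified_folds(
    samples: list[SampleRecord],
    n_folds: int = 10,
    seed: int = 0,
    stratify_by: str = "species",
) -> np.ndarray:
    """Fold assignment preserving per-stratum proportions.

    Within each stratum the (seeded) shuffled samples are dealt round-robin
    across folds, so per-stratum fold sizes differ by at most one.
    """
    rng = np.random.default_rng(seed)
    strata = [getattr(s, stratify_by) for s in samples]
    fold_of = np.empty(len(samples), dtype=int)
    for stratum in sorted(set(strata)):
        idx = np.array([i for i, s in enumerate(strata) if s == stratum])
        if len(idx) < n_folds:
            raise ValidationError(
                f"stratum {stratum!r} has {len(idx)} samples, fewer than "
                f"{n_folds} folds; merge strata or use LOOCV"
            )
        idx = rng.permutation(idx)
        start = int(rng.integers(n_folds))  # rotate which folds get extras
        for pos, i in enumerate(idx):
            fold_of[i] = (start + pos) % n_folds
    return fold_of


def lofo10(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    transform: AgeTransformSpec,
    alpha: float = 0.5,
    seed: int = 0,
    n_folds: int = 10,
    stratify_by: str = "species",
    impute: bool = False,
) -> CVReport:
    """Species-balanced 10-fold cross-validation (LOFO10)."""
    fold_of = stratified_folds(samples, n_folds=n_folds, seed=seed,
                               stratify_by=stratify_by)
    seeds = _spawn_seeds(seed, n_folds)
    return _evaluate_holdouts(
        beta, samples, transform, alpha, fold_of, seeds, 10, impute
    )


def age_acceleration(
    predicted: np.ndarray, chronological: np.ndarray, method: str = "delta"
) -> np.ndarray:
    """Epigenetic age acceleration in years.

    ``delta``    — DNAm age minus chronological age.
    ``residual`` — residual of the least-squares regression of DNAm age on
                   chronological age (mean 0, uncorrelated with age by
                   construction).
    """
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if predicted.shape != chronological.shape:
        raise ValidationError(
            f"length mismatch: {predicted.shape} vs {chronological.shape}"
        )
    if method == "delta":
        return predicted - chronological
    if method == "residual":
        D = np.column_stack([np.ones_like(chronological), chronological])
        coef, *_ = np.linalg.lstsq(D, predicted, rcond=None)
        return predicted - D @ coef
    raise ValueError(f"unknown acceleration method {method!r}")


def acceleration_correlations(accels: dict[str, np.ndarray]) -> "pd.DataFrame":
    """Pairwise Pearson correlations between acceleration measures.

    Entries involving a constant vector are NaN (flagged, not errored):
    correlation with a constant is undefined.
    """
    import pandas as pd

    clocks = list(accels)
    lengths = {len(np.asarray(v)) for v in accels.values()}
    if len(lengths) > 1:
        raise ValidationError("acceleration vectors cover different sample sets")
    k = len(clocks)
    M = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            a = np.asarray(accels[clocks[i]], dtype=float)
            b = np.asarray(accels[clocks[j]], dtype=float)
            if i == j:
                M[i, j] = 1.0
            elif a.std() > 0 and b.std() > 0:
                M[i, j] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(M, index=clocks, columns=clocks)
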