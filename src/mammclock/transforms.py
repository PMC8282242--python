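"""Invertible age transformations used as the clock's dependent variable.

Multi-species age estimators do not regress on raw years: methylation changes
fast during development and slowly in adulthood, and species differ in both
tempo and lifespan.  Two transforms address this:

* ``loglinear`` — logarithmic below a species "adult age" and linear with
  matched slope above it, so a one-unit error means a comparable relative
  error in the young and an absolute error in adults.
* ``relative_age`` — age divided by the species' maximum lifespan, putting a
  2-year-old elephant and a 3-year-old human on the same developmental scale.

All transforms are strictly increasing with exact closed-form inverses.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datamodel import AgeTransformSpec

__all__ = [
    "loglinear",
    "loglinear_inverse",
    "relative_age",
    "relative_age_inverse",
    "transform_ages",
    "inverse_transform_ages",
]


def loglinear(age, adult_age: float):
    """Log-linear transform of age.

    F(age) = log((age+1)/(adult_age+1))        for age <= adult_age
           = (age - adult_age)/(adult_age + 1) for age  > adult_age

    Both branches meet at F(adult_age) = 0 with common slope
    1/(adult_age + 1), so F is continuous and once-differentiable.
    """
    age = np.asarray(age, dtype=float)
    if adult_age <= 0:
        raise ValueError(f"adult_age must be > 0, got {adult_age}")
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    young = np.log((age + 1.0) / (adult_age + 1.0))
    old = (age - adult_age) / (adult_age + 1.0)
    out = np.where(age <= adult_age, young, old)
    return float(out) if out.ndim == 0 else out


def loglinear_inverse(y, adult_age: float):
    """Exact inverse of :func:`loglinear`.

    age = exp(y)*(adult_age+1) - 1        for y <= 0
        = y*(adult_age+1) + adult_age     for y  > 0

    A mathematically negative age (possible only through floating-point
    noise at y slightly below F(0)) is clamped to 0 with a warning.
    """
    y = np.asarray(y, dtype=float)
    if adult_age <= 0:
        raise ValueError(f"adult_age must be > 0, got {adult_age}")
    young = np.exp(y) * (adult_age + 1.0) - 1.0
    old = y * (adult_age + 1.0) + adult_age
    out = np.where(y <= 0, young, old)
    if np.any(out < 0):
        warnings.warn("inverse log-linear age below 0; clamped to 0", stacklevel=2)
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def relative_age(age, max_lifespan: float):
    """Age divided by the species' maximum lifespan.

    Nominally in [0, 1]; values above 1 (animal older than the configured
    maximum) are permitted but flagged with a warning, since the maximum
    lifespan is a modelling parameter rather than a hard biological bound.
    """
    age = np.asarray(age, dtype=float)
    if max_lifespan <= 0:
        raise ValueError(f"max_lifespan must be > 0, got {max_lifespan}")
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = age / max_lifespan
    if np.any(out > 1.0):
        warnings.warn(
            "relative age above 1: sample older than configured max lifespan",
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def relative_age_inverse(y, max_lifespan: float):
    """Years from relative age; negative results clamp to 0 with a warning."""
    y = np.asarray(y, dtype=float)
    if max_lifespan <= 0:
        raise ValueError(f"max_lifespan must be > 0, got {max_lifespan}")
    out = y * max_lifespan
    if np.any(out < 0):
        warnings.warn("inverse relative age below 0; clamped to 0", stacklevel=2)
        out = np.maximum(out, 0.0)
    return float(out) if out.ndim == 0 else out


def transform_ages(
    ages: np.ndarray, species: list[str], spec: AgeTransformSpec
) -> np.ndarray:
    """Apply ``spec`` elementwise using each sample's species parameters."""
    ages = np.asarray(ages, dtype=float)
    if spec.kind == "identity":
        return ages.copy()
    out = np.empty_like(ages)
    for i, (a, sp) in enumerate(zip(ages, species)):
        param = spec.param_for(sp)
        out[i] = loglinear(a, param) if spec.kind == "loglinear" else relative_age(a, param)
    return out


def inverse_transform_ages(
    y: np.ndarray, species: list[str], spec: AgeTransformSpec
) -> np.ndarray:
    """Invert ``spec`` elementwise back to years."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "identity":
        return y.copy()
    out = np.empty_like(y)
    for i, (v, sp) in enumerate(zip(y, species)):
        param = spec.param_for(sp)
        out[i] = (
            loglinear_inverse(v, param)
            if spec.kind == "loglinear"
            else relative_age_inverse(v, param)
        )
    return out
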