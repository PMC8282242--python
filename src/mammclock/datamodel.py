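"""Core data types and tabular I/O for methylation-array analyses.

The in-memory containers deliberately stay close to the on-disk formats a
methylation lab exchanges: a probes x samples beta-value matrix (TSV), a
sample sheet (CSV), a probe annotation manifest (CSV), and a serialized
sparse clock model (JSON).  Every reader validates; malformed input raises a
typed error rather than being silently coerced.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "KNOWN_SPECIES",
    "SampleRecord",
    "BetaMatrix",
    "ProbeAnnotation",
    "AgeTransformSpec",
    "ClockModel",
    "CVReport",
    "EWASRow",
    "MetaResult",
    "ConcordanceLabel",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_probe_annotations",
    "write_probe_annotations",
    "filter_by_age_confidence",
    "read_clock_model",
    "write_clock_model",
]


class FormatError(ValueError):
    """File structure is wrong: bad header, duplicate ids, unparseable cell."""


class ValidationError(ValueError):
    """Values are structurally readable but violate a domain invariant."""


KNOWN_SPECIES = ("asian_elephant", "african_elephant", "human")

REGION_CLASSES = ("promoter", "exon", "intron", "upstream", "downstream", "intergenic")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleRecord:
    """One animal/sample: identity, species, sex, chronological age.

    ``age_confidence`` is an opaque percentage in [0, 100] expressing
    confidence in the recorded chronological age; samples below a cutoff
    (90% by default) are dropped before any modelling.
    """

    sample_id: str
    species: str
    sex: str  # "F", "M" or "unknown"
    age_years: float
    tissue: str = "blood"
    age_confidence: float = 100.0

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: age_years must be >= 0, got {self.age_years}"
            )
        if not (0.0 <= self.age_confidence <= 100.0):
            raise ValidationError(
                f"sample {self.sample_id!r}: age_confidence must be in [0, 100], "
                f"got {self.age_confidence}"
            )
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id!r}: sex must be F, M or unknown, got {self.sex!r}"
            )


_SHEET_REQUIRED = ("sample_id", "species", "sex", "age_years", "age_confidence")


def _normalize_species(raw: str) -> str:
    s = str(raw).strip().lower().replace(" ", "_")
    if s in KNOWN_SPECIES:
        return s
    # common shorthands
    aliases = {"asian": "asian_elephant", "african": "african_elephant"}
    return aliases.get(s, s)  # unknown species kept verbatim ("other")


def _normalize_sex(raw) -> str:
    s = str(raw).strip().upper()
    if s in ("F", "FEMALE"):
        return "F"
    if s in ("M", "MALE"):
        return "M"
    return "unknown"


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a CSV sample sheet into typed, validated records.

    Required columns: sample_id, species, sex, age_years, age_confidence;
    ``tissue`` is optional and defaults to "blood".  Species strings are
    normalized case-insensitively; unrecognized species are kept verbatim.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in _SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample sheet {path}: missing required columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise FormatError(f"sample sheet {path}: duplicate sample_id(s) {dups}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=_normalize_species(row["species"]),
                sex=_normalize_sex(row["sex"]),
                age_years=float(row["age_years"]),
                tissue=str(row["tissue"]) if "tissue" in df.columns else "blood",
                age_confidence=float(row["age_confidence"]),
            )
        )
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "species": [s.species for s in samples],
            "sex": [s.sex for s in samples],
            "age_years": [s.age_years for s in samples],
            "tissue": [s.tissue for s in samples],
            "age_confidence": [s.age_confidence for s in samples],
        }
    ).to_csv(path, index=False)


def filter_by_age_confidence(
    samples: Sequence[SampleRecord], min_confidence: float = 90.0
) -> list[SampleRecord]:
    """Keep records whose age-estimate confidence is >= ``min_confidence`` percent.

    Order is preserved.  The default cutoff of 90% drops animals whose
    chronological age is too uncertain to train or evaluate an age estimator.
    """
    return [s for s in samples if s.age_confidence >= min_confidence]


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Dense probes x samples matrix of methylation fractions in [0, 1].

    Missing values are stored as NaN.  Rows are probes, columns are samples —
    the array-manifest convention; nothing ever transposes silently.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_probes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe ids in beta matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in beta matrix")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            i, j = self._first_out_of_range()
            raise ValidationError(
                f"beta value {self.values[i, j]} outside [0, 1] at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    def _first_out_of_range(self) -> tuple[int, int]:
        bad = np.argwhere(
            np.isfinite(self.values) & ((self.values < 0) | (self.values > 1))
        )
        return tuple(bad[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples not in beta matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in idx]
        if missing:
            raise ValidationError(f"probes not in beta matrix: {missing}")
        rows = [idx[p] for p in probe_ids]
        return BetaMatrix(list(probe_ids), list(self.sample_ids), self.values[rows, :])


def read_beta_matrix(
    path: str | Path,
    missing_marker: str = "NA",
    transpose: bool = False,
) -> BetaMatrix:
    """Read a TSV beta matrix (header = sample ids, first column = probe ids).

    Values must lie in [0, 1]; the designated ``missing_marker`` becomes NaN.
    ``transpose=True`` must be passed explicitly for samples x probes files —
    the reader never guesses orientation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[missing_marker],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"beta matrix {path}: duplicated probe id(s) {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"beta matrix {path}: duplicated sample id(s) {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        obj = df.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(obj.isna().to_numpy() & df.notna().to_numpy())
        i, j = bad[0]
        raise FormatError(
            f"beta matrix {path}: non-numeric value {df.iat[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        ) from None
    if transpose:
        values = values.T
        return BetaMatrix(list(map(str, df.columns)), list(map(str, df.index)), values)
    return BetaMatrix(list(map(str, df.index)), list(map(str, df.columns)), values)


def write_beta_matrix(
    beta: BetaMatrix, path: str | Path, missing_marker: str = "NA"
) -> None:
    """Write TSV with >= 10 significant digits so a round-trip is faithful."""
    df = pd.DataFrame(beta.values, index=beta.probe_ids, columns=beta.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=missing_marker, float_format="%.12g")


# ---------------------------------------------------------------------------
# Probe annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic context of one array probe (1-based coordinates).

    ``tss_distance`` is signed: negative means upstream of the nearest
    transcription start site.  ``cgi`` flags CpG-island membership.
    """

    probe_id: str
    chrom: str
    pos: int
    nearest_gene: str
    tss_distance: int
    region_class: str
    cgi: bool

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id!r}: pos must be >= 1")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(
                f"probe {self.probe_id!r}: unknown region_class {self.region_class!r}"
            )


_ANNOT_COLS = ("probe_id", "chrom", "pos", "nearest_gene",
               "tss_distance", "region_class", "cgi")


def read_probe_annotations(path: str | Path) -> dict[str, ProbeAnnotation]:
    df = pd.read_csv(path)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation manifest {path}: missing columns {missing}")
    if df["probe_id"].duplicated().any():
        raise FormatError(f"annotation manifest {path}: duplicate probe ids")
    out: dict[str, ProbeAnnotation] = {}
    for _, row in df.iterrows():
        ann = ProbeAnnotation(
            probe_id=str(row["probe_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            nearest_gene=str(row["nearest_gene"]),
            tss_distance=int(row["tss_distance"]),
            region_class=str(row["region_class"]),
            cgi=bool(row["cgi"]),
        )
        out[ann.probe_id] = ann
    return out


def write_probe_annotations(
    annots: Mapping[str, ProbeAnnotation] | Iterable[ProbeAnnotation],
    path: str | Path,
) -> None:
    items = list(annots.values()) if isinstance(annots, Mapping) else list(annots)
    pd.DataFrame(
        {
            "probe_id": [a.probe_id for a in items],
            "chrom": [a.chrom for a in items],
            "pos": [a.pos for a in items],
            "nearest_gene": [a.nearest_gene for a in items],
            "tss_distance": [a.tss_distance for a in items],
            "region_class": [a.region_class for a in items],
            "cgi": [a.cgi for a in items],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Age transform spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeTransformSpec:
    """Which dependent-variable transform a clock uses, with per-species
    parameters.

    kind:
      identity   — regress on age in years directly
      loglinear  — logarithmic below a species' adult age, linear above
                   (needs ``adult_age`` per species)
      relative   — age / species maximum lifespan, in [0, 1]
                   (needs ``max_lifespan`` per species)
    """

    kind: str
    adult_age: Mapping[str, float] = field(default_factory=dict)
    max_lifespan: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("identity", "loglinear", "relative"):
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        params = self.adult_age if self.kind == "loglinear" else self.max_lifespan
        for sp, v in dict(params).items():
            if not v > 0:
                raise ValidationError(
                    f"transform parameter for species {sp!r} must be > 0, got {v}"
                )

    def param_for(self, species: str) -> float:
        """The species parameter the chosen kind needs; raises if absent."""
        if self.kind == "identity":
            return math.nan
        table = self.adult_age if self.kind == "loglinear" else self.max_lifespan
        if species not in table:
            name = "adult_age" if self.kind == "loglinear" else "max_lifespan"
            raise ValidationError(
                f"transform kind {self.kind!r} requires {name} for species {species!r}"
            )
        return float(table[species])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "adult_age": dict(self.adult_age),
            "max_lifespan": dict(self.max_lifespan),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AgeTransformSpec":
        kind = d.get("kind")
        if kind not in ("identity", "loglinear", "relative"):
            raise FormatError(f"unknown transform kind {kind!r}")
        return cls(
            kind=kind,
            adult_age=dict(d.get("adult_age", {})),
            max_lifespan=dict(d.get("max_lifespan", {})),
        )


# ---------------------------------------------------------------------------
# Clock model
# ---------------------------------------------------------------------------

@dataclass
class ClockModel:
    """A sparse linear age estimator on beta values plus its age transform.

    Only nonzero coefficients are stored; applying the model computes
    intercept + sum(coef * beta) and then inverts the transform with the
    sample's species parameters to report years.
    """

    intercept: float
    coefficients: dict[str, float]
    alpha: float
    lam: float
    transform: AgeTransformSpec
    training_species: tuple[str, ...]
    n_train: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")

    @property
    def n_cpgs(self) -> int:
        return len(self.coefficients)


def write_clock_model(model: ClockModel, path: str | Path) -> None:
    payload = {
        "intercept": model.intercept,
        "alpha": model.alpha,
        "lambda": model.lam,
        "transform": model.transform.to_dict(),
        "coefficients": model.coefficients,
        "training_species": sorted(model.training_species),
        "n_train": model.n_train,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_clock_model(path: str | Path) -> ClockModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"clock model {path}: invalid JSON ({e})") from None
    try:
        coefs = {str(k): float(v) for k, v in payload["coefficients"].items()}
    except (TypeError, ValueError, KeyError) as e:
        raise FormatError(f"clock model {path}: malformed coefficients ({e})") from None
    return ClockModel(
        intercept=float(payload["intercept"]),
        coefficients=coefs,
        alpha=float(payload["alpha"]),
        lam=float(payload["lambda"]),
        transform=AgeTransformSpec.from_dict(payload["transform"]),
        training_species=tuple(payload.get("training_species", ())),
        n_train=int(payload.get("n_train", 0)),
    )


# ---------------------------------------------------------------------------
# Reports and association rows
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Cross-validation result: per-sample held-out predictions plus summary
    metrics (Pearson R and median absolute error, both in years)."""

    per_sample: list[tuple[str, int, float, float]]  # (id, fold, true, pred)
    pearson_r: float
    mae_years: float

    @classmethod
    def from_per_sample(
        cls, per_sample: Sequence[tuple[str, int, float, float]]
    ) -> "CVReport":
        true = np.array([row[2] for row in per_sample], dtype=float)
        pred = np.array([row[3] for row in per_sample], dtype=float)
        if true.size >= 2 and true.std() > 0 and pred.std() > 0:
            r = float(np.corrcoef(true, pred)[0, 1])
        else:
            r = math.nan
        mae = float(np.median(np.abs(pred - true))) if true.size else math.nan
        return cls(per_sample=list(per_sample), pearson_r=r, mae_years=mae)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_sample,
            columns=["sample_id", "fold_index", "true_age_years", "predicted_age_years"],
        )


@dataclass(frozen=True)
class EWASRow:
    """Per-probe marginal association: Pearson r, t, two-sided p, signed z."""

    probe_id: str
    r: float
    n: int
    t_stat: float
    p: float
    z: float


@dataclass(frozen=True)
class MetaResult:
    """Stouffer-combined association across cohorts."""

    probe_id: str
    z_meta: float
    p_meta: float
    cohort_zs: tuple[tuple[str, float, int], ...]  # (cohort_id, z, n)


@dataclass(frozen=True)
class ConcordanceLabel:
    """Cross-cohort aging-direction label for one probe."""

    probe_id: str
    label: str  # "shared" | "divergent" | "not_significant"
    z_a: float
    z_b: float
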