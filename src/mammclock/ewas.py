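"""Epigenome-wide association screening and cross-cohort synthesis.

Age associations use the classical marginal screen: per probe, the Pearson
correlation r of beta with the trait, the exact t statistic
t = r*sqrt(n-2)/sqrt(1-r^2), its two-sided Student-t p value (identical to
the univariate-regression p), and the signed normal-scale statistic
z = sign(r) * Phi^-1(1 - p/2).  Cohorts are combined by Stouffer's method
with sqrt(n) weights.  Downstream utilities implement the standard hit
selection (p < 1e-5, up to 500 probes per direction ranked by |z|),
cross-species shared/divergent concordance labels, genomic-context
summaries, and linear-model screens for sex (adjusted for age) and
sex-by-age interaction.

Missing betas are handled per probe with pairwise-complete observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datamodel import (
    BetaMatrix,
    ConcordanceLabel,
    EWASRow,
    MetaResult,
    ProbeAnnotation,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "correlation_screen",
    "stouffer_meta",
    "select_top",
    "concordance",
    "context_summary",
    "sex_screen",
    "interaction_screen",
    "rows_to_frame",
]

# z for a p value at the smallest positive double; caps the signed statistic
# when p underflows so ordering by |z| stays finite and well defined
_Z_CAP = float(-special.ndtri(5e-324 / 2))


def _p_to_z(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Signed normal-scale statistic from a two-sided p value."""
    with np.errstate(divide="ignore"):
        z = -special.ndtri(np.minimum(p, 1.0) / 2.0)
    z = np.minimum(z, _Z_CAP)
    return np.where(sign < 0, -z, z)


def _t_to_p(t: np.ndarray, df) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def rows_to_frame(rows: list[EWASRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in rows],
            "r": [r.r for r in rows],
            "n": [r.n for r in rows],
            "t": [r.t_stat for r in rows],
            "p": [r.p for r in rows],
            "z": [r.z for r in rows],
        }
    )


def correlation_screen(beta: BetaMatrix, trait: np.ndarray) -> list[EWASRow]:
    """Marginal Pearson-correlation screen of every probe against a trait.

    Pairwise-complete per probe; a zero-variance probe yields r = NaN, p = 1,
    z = 0 (kept in the output so probe sets stay aligned across cohorts).
    """
    trait = np.asarray(trait, dtype=float)
    B = beta.values  # probes x samples
    if trait.shape != (B.shape[1],):
        raise ValidationError(
            f"trait length {trait.shape} does not match {B.shape[1]} samples"
        )
    valid = np.isfinite(B) & np.isfinite(trait)[None, :]
    n = valid.sum(axis=1)
    if B.shape[1] < 3 or n.max() < 3:
        raise ValidationError("correlation screen needs at least 3 samples")
    Bz = np.where(valid, B, 0.0)
    tz = np.where(valid, trait[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_b = Bz.sum(axis=1) / n
        mean_t = tz.sum(axis=1) / n
        # centered moments: exact zeros for constant probes, no cancellation
        Bc = np.where(valid, B - mean_b[:, None], 0.0)
        Tc = np.where(valid, trait[None, :] - mean_t[:, None], 0.0)
        sxy = (Bc * Tc).sum(axis=1) / n
        sxx = (Bc * Bc).sum(axis=1) / n
        syy = (Tc * Tc).sum(axis=1) / n
        r = sxy / np.sqrt(sxx * syy)
    r = np.where((sxx <= 0) | (syy <= 0) | (n < 3), np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    df = np.maximum(n - 2, 1)
    p = np.where(np.isnan(r), 1.0, np.where(np.isinf(t), 0.0, _t_to_p(t, df)))
    p = np.maximum(p, 5e-324)
    z = np.where(np.isnan(r), 0.0, _p_to_z(p, np.where(np.isnan(r), 0.0, np.sign(r))))
    return [
        EWASRow(
            probe_id=beta.probe_ids[j],
            r=float(r[j]),
            n=int(n[j]),
            t_stat=float(t[j]) if np.isfinite(t[j]) else float(np.sign(r[j]) * np.inf),
            p=float(p[j]),
            z=float(z[j]),
        )
        for j in range(B.shape[0])
    ]


def stouffer_meta(
    cohorts: list[tuple[str, float, int]],
    probe_id: str = "",
    weighted: bool = True,
) -> MetaResult:
    """Combine per-cohort signed z statistics by Stouffer's method.

    With sample-size weights w_i = sqrt(n_i) (the default),
    z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)); unweighted sets every w_i = 1.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    zs = np.array([c[1] for c in cohorts], dtype=float)
    ns = np.array([c[2] for c in cohorts], dtype=float)
    if np.any(ns <= 0):
        raise ValidationError("cohort n must be positive")
    w = np.sqrt(ns) if weighted else np.ones_like(ns)
    z_meta = float(w @ zs / np.sqrt(w @ w))
    p_meta = float(max(2.0 * special.ndtr(-abs(z_meta)), 5e-324))
    return MetaResult(
        probe_id=probe_id,
        z_meta=z_meta,
        p_meta=p_meta,
        cohort_zs=tuple((str(c[0]), float(c[1]), int(c[2])) for c in cohorts),
    )


def meta_screen(
    cohort_rows: dict[str, list[EWASRow]], weighted: bool = True
) -> list[MetaResult]:
    """Stouffer-combine per-probe rows across cohorts (intersection of probes)."""
    by_cohort = {
        cid: {r.probe_id: r for r in rows} for cid, rows in cohort_rows.items()
    }
    common = set.intersection(*(set(d) for d in by_cohort.values()))
    out = []
    for pid in sorted(common):
        cohorts = [(cid, by_cohort[cid][pid].z, by_cohort[cid][pid].n)
                   for cid in sorted(by_cohort)]
        out.append(stouffer_meta(cohorts, probe_id=pid, weighted=weighted))
    return out


def select_top(
    rows: list[EWASRow],
    p_threshold: float = 1e-5,
    cap_per_direction: int = 500,
) -> tuple[list[EWASRow], list[EWASRow]]:
    """Top age-associated probes, separately per direction of effect.

    Within each sign of z: keep rows with p < threshold, rank by |z|
    descending (ties broken by probe_id so the output is order-invariant),
    truncate at the cap.  Returns (hypermethylated, hypomethylated) sets.
    """
    def pick(direction: int) -> list[EWASRow]:
        qual = [r for r in rows if r.p < p_threshold and np.sign(r.z) == direction]
        qual.sort(key=lambda r: (-abs(r.z), r.probe_id))
        return qual[:cap_per_direction]

    return pick(+1), pick(-1)


def concordance(
    rows_a: list[EWASRow],
    rows_b: list[EWASRow],
    p_threshold: float = 1e-5,
) -> tuple[list[ConcordanceLabel], int]:
    """Label each probe shared / divergent / not_significant across two cohorts.

    shared    — significant in both cohorts with the same direction of aging;
    divergent — significant in both with opposite directions.
    Probes present in only one cohort are excluded; their count is returned.
    """
    a = {r.probe_id: r for r in rows_a}
    b = {r.probe_id: r for r in rows_b}
    common = sorted(set(a) & set(b))
    n_excluded = len(set(a) ^ set(b))
    labels = []
    for pid in common:
        ra, rb = a[pid], b[pid]
        both_sig = ra.p < p_threshold and rb.p < p_threshold
        if both_sig and np.sign(ra.z) == np.sign(rb.z) and ra.z != 0:
            label = "shared"
        elif both_sig and np.sign(ra.z) != np.sign(rb.z):
            label = "divergent"
        else:
            label = "not_significant"
        labels.append(ConcordanceLabel(probe_id=pid, label=label, z_a=ra.z, z_b=rb.z))
    return labels, n_excluded


DEFAULT_TSS_BINS = (-100_000, -10_000, -1_000, 0, 1_000, 10_000, 100_000)


def context_summary(
    rows: list[EWASRow],
    annots: dict[str, ProbeAnnotation],
    tss_bins: tuple[int, ...] = DEFAULT_TSS_BINS,
) -> pd.DataFrame:
    """Cross-tabulate direction of the age effect by genomic context.

    One row per context (TSS-distance bin, region class, CGI status,
    "unannotated") with hyper- (z > 0) and hypomethylated (z < 0) counts.
    """
    recs = []
    for r in rows:
        direction = "n_hyper" if r.z > 0 else "n_hypo"
        ann = annots.get(r.probe_id)
        if ann is None:
            recs.append(("unannotated", "unannotated", direction))
            continue
        edges = list(tss_bins)
        bin_idx = np.digitize([ann.tss_distance], edges)[0]
        lo = "-inf" if bin_idx == 0 else str(edges[bin_idx - 1])
        hi = "+inf" if bin_idx == len(edges) else str(edges[bin_idx])
        recs.append((f"tss[{lo},{hi})", f"region:{ann.region_class}", direction))
        recs.append((f"cgi:{ann.cgi}", f"region:{ann.region_class}", direction))
    if not recs:
        return pd.DataFrame(columns=["context", "n_hyper", "n_hypo"])
    df = pd.DataFrame(recs, columns=["context", "region", "direction"])
    out = (
        df.groupby(["context", "direction"]).size().unstack(fill_value=0)
        .reindex(columns=["n_hyper", "n_hypo"], fill_value=0)
        .reset_index()
    )
    out.columns.name = None
    return out


def _ols_screen(
    beta: BetaMatrix,
    design: np.ndarray,
    term: int,
    use_m_values: bool = False,
) -> list[EWASRow]:
    """Per-probe OLS of beta (or M-values) on ``design``; report the t, p and
    signed z of column ``term``.  df = n - n_columns."""
    B = beta.values.T.copy()  # samples x probes
    n, k = design.shape
    df = n - k
    if df < 1:
        raise ValidationError(f"only {n} samples for {k} model terms")
    if np.isnan(B).any():
        raise ValidationError("missing beta values are not supported in OLS screens")
    if use_m_values:
        Bc = np.clip(B, 1e-3, 1 - 1e-3)
        B = np.log2(Bc / (1 - Bc))
    XtX_inv = np.linalg.pinv(design.T @ design)
    H = XtX_inv @ design.T           # (k, n)
    coefs = H @ B                    # (k, p)
    resid = B - design @ coefs
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[term, term], 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coefs[term] / se
    zero_var = B.std(axis=0) == 0
    p = np.where(zero_var | ~np.isfinite(t), 1.0, _t_to_p(np.where(np.isfinite(t), t, 0.0), df))
    p = np.maximum(p, 5e-324)
    # partial correlation of the term, for the r field
    with np.errstate(invalid="ignore", divide="ignore"):
        r_part = t / np.sqrt(t**2 + df)
    r_part = np.where(np.isfinite(r_part), r_part, np.nan)
    z = np.where(zero_var, 0.0, _p_to_z(p, np.sign(np.where(np.isfinite(t), t, 0.0))))
    return [
        EWASRow(
            probe_id=beta.probe_ids[j],
            r=float(r_part[j]),
            n=int(n),
            t_stat=float(t[j]) if np.isfinite(t[j]) else 0.0,
            p=float(p[j]),
            z=float(z[j]),
        )
        for j in range(B.shape[1])
    ]


def _sex_design(samples: list[SampleRecord]) -> tuple[np.ndarray, np.ndarray]:
    known = [s for s in samples if s.sex in ("F", "M")]
    if len(known) != len(samples):
        raise ValidationError("samples with unknown sex must be excluded first")
    sex = np.array([1.0 if s.sex == "F" else 0.0 for s in samples])
    if len(set(sex)) < 2:
        raise ValidationError("both sexes must be present")
    age = np.array([s.age_years for s in samples], dtype=float)
    return sex, age


def sex_screen(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    adjust_for_age: bool = True,
    use_m_values: bool = False,
) -> list[EWASRow]:
    """Baseline sex differences in methylation, optionally age-adjusted.

    Fits beta ~ sex + age per probe (df = n - 3) and reports the sex
    coefficient's t, two-sided p and signed z.  With
    ``adjust_for_age=False`` the model drops the age covariate — useful for
    demonstrating the confounding the adjustment removes.
    """
    sex, age = _sex_design(samples)
    cols = [np.ones_like(sex), sex] + ([age] if adjust_for_age else [])
    design = np.column_stack(cols)
    return _ols_screen(beta, design, term=1, use_m_values=use_m_values)


def interaction_screen(
    beta: BetaMatrix,
    samples: list[SampleRecord],
    use_m_values: bool = False,
) -> list[EWASRow]:
    """Sex-by-age interaction screen: probes whose aging slope differs
    between females and males.

    Fits beta ~ sex + age + sex*age per probe (df = n - 4) and reports the
    interaction term's statistics.
    """
    sex, age = _sex_design(samples)
    design = np.column_stack([np.ones_like(sex), sex, age, sex * age])
    return _ols_screen(beta, design, term=3, use_m_values=use_m_values)
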