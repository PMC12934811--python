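"""Curve summaries (AUC, IC50) and robust empirical-null de-batched z-scores.

AUC is the trapezoidal integral of viability over the log10-concentration
range, normalized by the range width, so 1 means no effect and lower values
mean more cytotoxic. IC50 is the log-linearly interpolated first crossing of
viability 0.5, with explicit censoring flags when the curve never reaches 0.5
(`above_max`) or starts below it (`below_min`).

Batch correction: for each sample, the distribution of its AUCs across the
drug panel is mostly "null" (typical drugs), contaminated by true sensitive or
resistant outliers. The empirical null is estimated robustly (median and
MAD×1.4826, optionally refined once after trimming |z| > 2.5), and each
(sample, drug) AUC is standardized against its own sample's null:

    z = (mu0 - AUC) / sigma0

so positive z means more cytotoxic than the sample's typical drug. Because the
null is per sample (and hence per study), study-level assay shifts cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, MultiscreenError, ValidationError

MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass
class CurveSummary:
    sample_id: str
    drug_id: str
    auc: float
    ic50_log10: float | None = None
    ic50_censored: str | None = None  # None, "above_max", "below_min"
    source: str = "imputed"           # "observed_fit" | "imputed"
    band: tuple | None = None         # optional (auc_lo, auc_hi)


@dataclass
class EmpiricalNull:
    sample_id: str
    mu0: float
    sigma0: float
    n_drugs_used: int
    trimmed_fraction: float = 0.0


def auc(viabilities: np.ndarray, log10_doses: np.ndarray) -> float:
    """Normalized trapezoidal AUC over the log10 dose range."""
    v = np.asarray(viabilities, float)
    x = np.asarray(log10_doses, float)
    if len(v) < 2:
        raise ValidationError("AUC requires >= 2 points; impute single-dose curves first")
    if np.any(np.diff(x) <= 0):
        raise ValidationError("doses must be strictly increasing")
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


def ic50(viabilities: np.ndarray, log10_doses: np.ndarray):
    """First 0.5-crossing of a monotone non-increasing curve.

    Returns (ic50_log10, censored) where censored is None, "above_max" (curve
    never drops to 0.5; value is the top of the range) or "below_min" (curve
    starts below 0.5; value is the bottom of the range)."""
    v = np.asarray(viabilities, float)
    x = np.asarray(log10_doses, float)
    if np.any(np.diff(v) > 1e-9):
        raise ValidationError("ic50 requires a monotone non-increasing curve")
    if v[0] < 0.5:
        return float(x[0]), "below_min"
    if v.min() > 0.5:
        return float(x[-1]), "above_max"
    k = int(np.argmax(v <= 0.5))  # first index at or below 0.5
    if v[k] == 0.5 or k == 0:
        return float(x[k]), None
    # linear interpolation in log10 dose
    frac = (v[k - 1] - 0.5) / (v[k - 1] - v[k])
    return float(x[k - 1] + frac * (x[k] - x[k - 1])), None


def fit_empirical_null(
    aucs: Iterable[float], sample_id: str = "", min_n: int = 20, refine: bool = True
) -> EmpiricalNull:
    """Robust per-sample null of the AUC histogram (median / scaled MAD).

    With `refine`, one re-estimation pass keeps values with provisional
    |z| <= 2.5 and reports the trimmed fraction."""
    a = np.asarray(list(aucs), float)
    if len(a) < min_n:
        raise MultiscreenError(
            f"sample {sample_id!r}: null undefined with n={len(a)} < min_n={min_n}"
        )
    mu0 = float(np.median(a))
    sigma0 = float(MAD_TO_SD * np.median(np.abs(a - mu0)))
    if sigma0 <= 0:
        raise MultiscreenError(f"sample {sample_id!r}: degenerate AUC spread (sigma0=0)")
    trimmed = 0.0
    n_used = len(a)
    if refine:
        z = np.abs(a - mu0) / sigma0
        keep = z <= 2.5
        trimmed = 1.0 - keep.mean()
        if keep.sum() >= 2:
            kept = a[keep]
            mu0 = float(np.mean(kept))
            sigma0 = float(np.std(kept, ddof=1))
            n_used = int(keep.sum())
            if sigma0 <= 0:
                raise MultiscreenError(
                    f"sample {sample_id!r}: degenerate AUC spread after trim"
                )
    return EmpiricalNull(sample_id=sample_id, mu0=mu0, sigma0=sigma0,
                         n_drugs_used=n_used, trimmed_fraction=float(trimmed))


def fit_nulls(
    summaries: Iterable[CurveSummary], min_n: int = 20, refine: bool = True
) -> dict[str, EmpiricalNull]:
    by_sample: dict[str, list] = {}
    for s in summaries:
        by_sample.setdefault(s.sample_id, []).append(s.auc)
    return {
        sid: fit_empirical_null(vals, sample_id=sid, min_n=min_n, refine=refine)
        for sid, vals in by_sample.items()
    }


def zscore_debatch(
    summaries: Iterable[CurveSummary], nulls: Mapping[str, EmpiricalNull]
) -> pd.DataFrame:
    """Long-format de-batched z matrix (sample_id, drug_id, z, provenance).

    Cells whose sample has no fitted null get z = NaN (explicitly undefined)."""
    rows = []
    for s in summaries:
        null = nulls.get(s.sample_id)
        z = np.nan if null is None else (null.mu0 - s.auc) / null.sigma0
        rows.append(
            {"sample_id": s.sample_id, "drug_id": s.drug_id, "z": z,
             "provenance": s.source}
        )
    return pd.DataFrame(rows)


def global_zscore(summaries: Iterable[CurveSummary]) -> pd.DataFrame:
    """Comparator: z against the pooled AUC mean/sd across all samples."""
    items = list(summaries)
    a = np.array([s.auc for s in items], float)
    if len(a) < 2:
        raise ValidationError("global z-scoring requires >= 2 values")
    sd = a.std(ddof=1)
    if sd == 0:
        raise ValidationError("constant AUCs: global z undefined")
    mu = a.mean()
    return pd.DataFrame(
        [
            {"sample_id": s.sample_id, "drug_id": s.drug_id,
             "z": (mu - s.auc) / sd, "provenance": s.source}
            for s in items
        ]
    )


def summarize_imputed(model, sample_ids=None, drug_ids=None, S=None, seed=None):
    """CurveSummary per (sample, drug) from model-imputed curves.

    AUC (with a 90% band over posterior draws) and IC50 are computed on the
    model's dose grid for every pair — observed and unobserved alike, so
    summaries are commensurable; provenance records which is which."""
    draws, sample_ids, drug_ids = model.posterior_grid_draw_matrix(
        S=S, seed=seed, sample_ids=sample_ids, drug_ids=drug_ids
    )
    observed = model.observed_pairs
    out = []
    for jj, did in enumerate(drug_ids):
        x = model.grids[did].log10_points
        width = x[-1] - x[0]
        block = draws[:, :, jj, :]                       # (S, n_s, K)
        auc_draws = np.trapezoid(block, x, axis=2) / width
        mean_curves = block.mean(axis=0)                 # (n_s, K)
        auc_mean = np.trapezoid(mean_curves, x, axis=1) / width
        lo = np.quantile(auc_draws, 0.05, axis=0)
        hi = np.quantile(auc_draws, 0.95, axis=0)
        for ii, sid in enumerate(sample_ids):
            val, cens = ic50(np.minimum.accumulate(mean_curves[ii]), x)
            out.append(
                CurveSummary(
                    sample_id=sid, drug_id=did,
                    auc=float(auc_mean[ii]),
                    ic50_log10=val, ic50_censored=cens,
                    source="observed_fit" if (sid, did) in observed else "imputed",
                    band=(float(lo[ii]), float(hi[ii])),
                )
            )
    return out


def debatch_pipeline(model, min_n: int = 20, refine: bool = True, S=None, seed=None):
    """Impute -> summarize -> fit nulls -> z-score. Returns (z df, nulls, summaries)."""
    summaries = summarize_imputed(model, S=S, seed=seed)
    nulls = fit_nulls(summaries, min_n=min_n, refine=refine)
    z = zscore_debatch(summaries, nulls)
    return z, nulls, summaries


def write_zscores(z: pd.DataFrame, path) -> None:
    z.to_csv(path, sep="\t", index=False)


def write_nulls(nulls: Mapping[str, EmpiricalNull], path) -> None:
    pd.DataFrame([vars(n) for n in nulls.values()]).to_csv(path, sep="\t", index=False)
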