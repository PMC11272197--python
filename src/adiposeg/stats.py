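"""Subject-level derived measures and cohort statistics.

Implements HOMA-IR and BMI, partial Spearman correlation with covariates,
Benjamini–Hochberg FDR control over a comparison family, simple linear
regression summaries, and the driver that runs every predictor against every
outcome the way a regional-imaging correlation table is built (one BH family
per predictor, optional sex stratification).

The partial Spearman correlation rank-transforms x, y, and each covariate
(average ranks for ties) and then reads the partial correlation off the
inverse of the joint correlation matrix; the two-sided p-value uses the t
approximation rho * sqrt((n-2-k)/(1-rho^2)) on n-2-k degrees of freedom.
This matrix-inversion form is algebraically identical to residualizing the
ranked variables on the ranked covariates by least squares and correlating
the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityError,
    ConfigurationError,
    DegenerateInputError,
    DomainError,
    UnitError,
)

__all__ = [
    "MGDL_PER_MMOL",
    "homa_ir",
    "bmi",
    "is_obese",
    "CorrelationResult",
    "spearman_partial",
    "FdrFamily",
    "bh_adjust",
    "linreg_summary",
    "run_table2_analysis",
    "derive_measures",
]

#: glucose mg/dL per mmol/L (molar mass of glucose 180.182 g/mol)
MGDL_PER_MMOL = 18.0182

#: WHO obesity cut-point, kg/m^2
OBESITY_BMI_THRESHOLD = 30.0


def homa_ir(
    fasting_glucose: float,
    fasting_insulin_uU_ml: float,
    glucose_unit: str = "mg/dL",
) -> float:
    """Homeostatic Model Assessment of Insulin Resistance.

    HOMA-IR = fasting insulin (µU/mL) x fasting glucose (mmol/L) / 22.5;
    glucose given in mg/dL is converted by dividing by 18.0182.
    """
    if fasting_glucose <= 0 or fasting_insulin_uU_ml <= 0:
        raise DomainError("homa_ir: glucose and insulin must be strictly positive")
    if glucose_unit == "mg/dL":
        glucose_mmol = fasting_glucose / MGDL_PER_MMOL
    elif glucose_unit == "mmol/L":
        glucose_mmol = fasting_glucose
    else:
        raise UnitError(f"homa_ir: unknown glucose unit {glucose_unit!r}")
    return fasting_insulin_uU_ml * glucose_mmol / 22.5


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("bmi: weight and height must be strictly positive")
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


def is_obese(bmi_value: float) -> bool:
    """Obesity predicate: BMI of 30 kg/m^2 or higher."""
    return bmi_value >= OBESITY_BMI_THRESHOLD


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_effective: int
    covariates: list[str] = field(default_factory=list)


def _listwise(arrays: list[np.ndarray]) -> list[np.ndarray]:
    stacked = np.column_stack(arrays)
    keep = np.all(np.isfinite(stacked), axis=1)
    return [a[keep] for a in arrays]


def spearman_partial(
    x,
    y,
    covariates: list | None = None,
    covariate_names: list[str] | None = None,
) -> CorrelationResult:
    """Spearman correlation of x and y partialling out covariates on ranks.

    With no covariates this reduces exactly to the ordinary Spearman rho.
    Missing values are removed listwise across x, y, and all covariates.
    """
    covariates = [np.asarray(c, dtype=float) for c in (covariates or [])]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    arrays = _listwise([x, y, *covariates])
    x, y, covariates = arrays[0], arrays[1], arrays[2:]
    k = len(covariates)
    n = x.size
    if n < k + 4:
        raise DomainError(
            f"spearman_partial: need at least {k + 4} complete cases for {k} "
            f"covariates, got {n}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("spearman_partial: zero variance in x or y")

    ranked = [sps.rankdata(a, method="average") for a in (x, y, *covariates)]
    corr = np.corrcoef(np.column_stack(ranked), rowvar=False)
    if k == 0:
        rho = float(corr[0, 1])
    else:
        cov_block = corr[2:, 2:]
        if np.linalg.matrix_rank(cov_block) < k or np.linalg.cond(corr) > 1e12:
            raise CollinearityError("spearman_partial: covariate matrix is singular")
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError("spearman_partial: correlation matrix singular") from exc
        rho = float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
    rho = float(np.clip(rho, -1.0, 1.0))

    df = n - 2 - k
    if df <= 0:
        raise DomainError("spearman_partial: non-positive degrees of freedom")
    if abs(rho) >= 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return CorrelationResult(
        rho=rho, p_value=p, n_effective=n, covariates=list(covariate_names or [])
    )


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrFamily:
    labels: list[str]
    raw_p: list[float]
    q: float
    rejected: list[bool]
    adjusted_p: list[float]


def bh_adjust(labels: list[str], raw_p, q: float = 0.05) -> FdrFamily:
    """Benjamini–Hochberg step-up procedure at FDR level q.

    Sort the m p-values ascending, find the largest i with
    p_(i) <= i*q/m and reject hypotheses 1..i; the adjusted p-value of the
    i-th ordered test is min_{j>=i} m*p_(j)/j, capped at 1.  Output order
    matches the input order.
    """
    p = np.asarray(list(raw_p), dtype=float)
    if not (0.0 < q < 1.0):
        raise DomainError("bh_adjust: q must lie in (0, 1)")
    if p.size == 0:
        return FdrFamily(labels=list(labels), raw_p=[], q=q, rejected=[], adjusted_p=[])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("bh_adjust: p-values must lie in (0, 1]")
    if len(labels) != p.size:
        raise ConfigurationError("bh_adjust: labels and raw_p lengths differ")

    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= thresholds)[0]
    cutoff = passing.max() + 1 if passing.size else 0
    rejected_sorted = np.zeros(m, dtype=bool)
    rejected_sorted[:cutoff] = True

    scaled = sorted_p * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)

    rejected = np.empty(m, dtype=bool)
    adjusted = np.empty(m, dtype=float)
    rejected[order] = rejected_sorted
    adjusted[order] = adjusted_sorted
    return FdrFamily(
        labels=list(labels),
        raw_p=p.tolist(),
        q=q,
        rejected=rejected.tolist(),
        adjusted_p=adjusted.tolist(),
    )


# ---------------------------------------------------------------------------
# linear regression summary
# ---------------------------------------------------------------------------

def linreg_summary(x, y) -> tuple[float, float, float]:
    """OLS of y on x with intercept: returns (R^2, slope, two-sided slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = _listwise([x, y])
    if x.size < 3:
        raise DomainError("linreg_summary: need at least 3 complete cases")
    if np.ptp(x) == 0:
        raise DegenerateInputError("linreg_summary: zero variance in x")
    fit = sps.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.pvalue)


# ---------------------------------------------------------------------------
# correlation-table driver
# ---------------------------------------------------------------------------

def run_table2_analysis(
    cohort: pd.DataFrame,
    predictors: list[str],
    outcomes: list[str],
    covariates: list[str] | None = None,
    q: float = 0.05,
    correct: bool = True,
    stratify_by: str | None = None,
    method: str = "spearman_partial",
) -> pd.DataFrame:
    """Correlate every predictor with every outcome, one BH family per predictor.

    Returns a long-format table (predictor, outcome, rho, p, adjusted p,
    rejected, n_effective[, stratum]).  ``correct=False`` skips the BH step
    (used for outcome families whose regions are too interconnected for the
    independence assumption).  ``stratify_by`` runs the full analysis within
    each level of that column, dropping it from the covariate list.
    ``method='linear'`` substitutes the simple linear-regression summary
    (no covariates) for cohorts where normality makes that the declared
    model choice; the switch is explicit, never data-driven.
    """
    if not outcomes:
        raise ConfigurationError("run_table2_analysis: outcomes list is empty")
    covariates = list(covariates or [])
    for col in [*predictors, *outcomes, *covariates]:
        if col not in cohort.columns:
            raise ConfigurationError(f"run_table2_analysis: column {col!r} not in cohort")
    if method not in ("spearman_partial", "linear"):
        raise ConfigurationError(f"run_table2_analysis: unknown method {method!r}")

    if stratify_by is not None:
        if stratify_by not in cohort.columns:
            raise ConfigurationError(
                f"run_table2_analysis: stratification column {stratify_by!r} not in cohort"
            )
        sub_cov = [c for c in covariates if c != stratify_by]
        frames = []
        for level, sub in cohort.groupby(stratify_by):
            tab = run_table2_analysis(
                sub, predictors, outcomes, sub_cov, q=q, correct=correct, method=method
            )
            tab.insert(0, "stratum", level)
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    records = []
    for predictor in predictors:
        fam_labels, fam_p, fam_rows = [], [], []
        for outcome in outcomes:
            if method == "linear":
                r2, slope, p = linreg_summary(cohort[predictor], cohort[outcome])
                res = CorrelationResult(
                    rho=float(np.sign(slope) * np.sqrt(r2)),
                    p_value=max(p, np.finfo(float).tiny),
                    n_effective=int(
                        np.isfinite(cohort[[predictor, outcome]].to_numpy(float)).all(1).sum()
                    ),
                )
            else:
                res = spearman_partial(
                    cohort[predictor],
                    cohort[outcome],
                    covariates=[cohort[c] for c in covariates],
                    covariate_names=covariates,
                )
            fam_labels.append(outcome)
            fam_p.append(res.p_value)
            fam_rows.append(res)
        if correct:
            fam = bh_adjust(fam_labels, fam_p, q=q)
            adj, rej = fam.adjusted_p, fam.rejected
        else:
            adj = [np.nan] * len(fam_p)
            rej = [p_ <= q for p_ in fam_p]
        for outcome, res, a, r in zip(fam_labels, fam_rows, adj, rej):
            records.append(
                {
                    "predictor": predictor,
                    "outcome": outcome,
                    "rho": res.rho,
                    "p": res.p_value,
                    "p_adjusted": a,
                    "rejected": bool(r),
                    "n_effective": res.n_effective,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# derived columns
# ---------------------------------------------------------------------------

def derive_measures(cohort: pd.DataFrame, glucose_unit: str = "mg/dL") -> pd.DataFrame:
    """Append bmi, homa_ir, obese and vat_sat_ratio columns where derivable.

    Rows with missing or non-positive inputs get NaN, not an error.
    """
    out = cohort.copy()
    if {"weight", "height"} <= set(out.columns) and "bmi" not in out.columns:
        w = out["weight"].to_numpy(float)
        h = out["height"].to_numpy(float)
        ok = np.isfinite(w) & np.isfinite(h) & (w > 0) & (h > 0)
        vals = np.full(len(out), np.nan)
        vals[ok] = w[ok] / (h[ok] / 100.0) ** 2
        out["bmi"] = vals
    if "bmi" in out.columns and "obese" not in out.columns:
        b = out["bmi"].to_numpy(float)
        out["obese"] = np.where(np.isfinite(b), b >= OBESITY_BMI_THRESHOLD, np.nan)
    if {"fasting_glucose", "fasting_insulin"} <= set(out.columns) and "homa_ir" not in out.columns:
        g = out["fasting_glucose"].to_numpy(float)
        ins = out["fasting_insulin"].to_numpy(float)
        if glucose_unit == "mg/dL":
            g = g / MGDL_PER_MMOL
        elif glucose_unit != "mmol/L":
            raise UnitError(f"derive_measures: unknown glucose unit {glucose_unit!r}")
        ok = np.isfinite(g) & np.isfinite(ins) & (g > 0) & (ins > 0)
        vals = np.full(len(out), np.nan)
        vals[ok] = ins[ok] * g[ok] / 22.5
        out["homa_ir"] = vals
    if {"vat_cm3", "sat_cm3"} <= set(out.columns) and "vat_sat_ratio" not in out.columns:
        v = out["vat_cm3"].to_numpy(float)
        s = out["sat_cm3"].to_numpy(float)
        ok = np.isfinite(v) & np.isfinite(s) & (s > 0)
        vals = np.full(len(out), np.nan)
        vals[ok] = v[ok] / s[ok]
        out["vat_sat_ratio"] = vals
    return out
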