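"""Weighted genetic risk score (wGRS) construction and evaluation.

The score follows the classical risk-allele-count recipe: tag SNPs with
a positive BMI effect in *both* cohorts *and* the pooled analysis enter
the score; each individual's 0/1/2 risk-allele counts are weighted by
the per-allele effect sizes, rescaled by dividing by the mean effect
size across the included SNPs (so an unweighted count is recovered when
all effects are equal), summed, and rounded to the nearest integer
(ties away from zero). The integer score is evaluated by the adjusted
BMI gradient across its quintiles, its Pearson correlation with BMI,
and the ROC area under the curve for predicting obesity (BMI >= 30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .qc import UndefinedStatisticError
from .types import GenotypeMatrix, PanelError, SnpPanel


@dataclass
class GrsWeights:
    """Risk alleles and per-allele weights (kg/m^2) of the score SNPs."""

    table: pd.DataFrame  # columns: snp_id, risk_allele, weight

    def __post_init__(self) -> None:
        need = {"snp_id", "risk_allele", "weight"}
        if not need.issubset(self.table.columns):
            raise PanelError(f"weights table needs columns {sorted(need)}")
        if len(self.table) and (self.table["weight"] <= 0).any():
            raise PanelError("all weights must be positive after risk-allele orientation")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list:
        return list(self.table["snp_id"])

    @property
    def mean_weight(self) -> float:
        return float(self.table["weight"].mean())


def select_grs_snps(
    assoc: pd.DataFrame,
    panel: Optional[SnpPanel] = None,
    cohorts: Sequence = ("PIZARRA", "HORTEGA"),
    pooled: str = "POOLED",
    weight_analysis: Optional[str] = None,
) -> GrsWeights:
    """Choose score SNPs: positive beta in both cohorts and pooled.

    ``assoc`` is a long table with columns ``snp_id, cohort, a1, a2,
    beta`` covering the two cohort analyses and the pooled one; only
    tag SNPs qualify when ``panel`` is given. Rows are harmonized to the
    pooled effect allele before the sign test. Weights default to the
    pooled betas (``weight_analysis=pooled``).
    """
    weight_analysis = weight_analysis or pooled
    analyses = [*cohorts, pooled]
    rows = []
    for snp_id, grp in assoc.groupby("snp_id", sort=False):
        if panel is not None and (snp_id not in panel or not panel[snp_id].is_tag):
            continue
        grp = grp.set_index("cohort")
        if not all(a in grp.index for a in analyses):
            continue
        ref_a1 = grp.loc[pooled, "a1"]
        ref_a2 = grp.loc[pooled, "a2"]
        betas = {}
        ok = True
        for a in analyses:
            r = grp.loc[a]
            if r["a1"] == ref_a1:
                betas[a] = float(r["beta"])
            elif r["a1"] == ref_a2 and r["a2"] == ref_a1:
                betas[a] = -float(r["beta"])
            else:
                ok = False  # irreconcilable allele labels
                break
        if not ok or not all(b > 0 for b in betas.values()):
            continue
        rows.append((snp_id, ref_a1, betas[weight_analysis]))

    table = pd.DataFrame(rows, columns=["snp_id", "risk_allele", "weight"])
    if not len(table):
        warnings.warn("no SNP has a positive beta in every analysis; empty score")
    return GrsWeights(table=table)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def compute_wgrs(
    gm: GenotypeMatrix,
    weights: GrsWeights,
    missing: str = "impute",
) -> pd.DataFrame:
    """Per-individual raw and integer weighted risk scores.

    Genotypes are oriented to each SNP's risk allele. Missing calls are
    imputed as twice the cohort risk-allele frequency (``missing=
    "impute"``, so every individual is scored) or the individual is
    dropped (``missing="drop"``). Returns a DataFrame with columns
    ``individual_id, cohort, raw_score, integer_score``.
    """
    if len(weights) == 0:
        return pd.DataFrame(columns=["individual_id", "cohort", "raw_score",
                                     "integer_score"])
    dose = np.column_stack([
        gm.oriented_column(s, a)
        for s, a in zip(weights.table["snp_id"], weights.table["risk_allele"])
    ])
    cohort = np.asarray(gm.cohort)
    if missing == "impute":
        for c in np.unique(cohort):
            rows = cohort == c
            sub = dose[rows]
            freq = np.nanmean(sub, axis=0) / 2.0
            nan_r, nan_c = np.where(np.isnan(sub))
            sub[nan_r, nan_c] = 2.0 * freq[nan_c]
            dose[rows] = sub
        keep = np.ones(len(cohort), dtype=bool)
    elif missing == "drop":
        keep = ~np.isnan(dose).any(axis=1)
        dose = dose[keep]
    else:
        raise ValueError("missing must be 'impute' or 'drop'")

    w = weights.table["weight"].to_numpy()
    raw = dose @ w / weights.mean_weight
    return pd.DataFrame({
        "individual_id": [i for i, k in zip(gm.individual_ids, keep) if k],
        "cohort": cohort[keep],
        "raw_score": raw,
        "integer_score": _round_half_away(raw).astype(int),
    })


def quintile_assignments(score: Sequence) -> np.ndarray:
    """Quintile (1..5) per individual; ties go to the lower quintile."""
    s = np.asarray(score, dtype=float)
    cuts = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    q = 1 + (s[:, None] > cuts[None, :]).sum(axis=1)
    if len(np.unique(q)) < 5:
        warnings.warn("ties collapse one or more score quintiles; bins merged")
    return q


def quintile_gradient(
    score: Sequence,
    bmi: Sequence,
    age: Sequence,
    sex: Sequence,
) -> dict:
    """Adjusted mean BMI per score quintile, with 95% CIs.

    Fits BMI on quintile indicators plus age and sex (sex as a
    female indicator if given as labels), both centered, so each
    indicator coefficient is the adjusted quintile mean at sample-mean
    covariates. Returns ``{"table": DataFrame, "q5_minus_q1": float,
    "q5_minus_q1_se": float}``.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(bmi, dtype=float)
    a = np.asarray(age, dtype=float)
    x = np.asarray(sex)
    if x.dtype == object or x.dtype.kind in "US":
        x = (x == "female").astype(float)
    x = x.astype(float)

    q = quintile_assignments(s)
    levels = np.unique(q)
    ind = (q[:, None] == levels[None, :]).astype(float)
    X = np.column_stack([ind, a - a.mean(), x - x.mean()])
    fit = sm.OLS(y, X).fit()

    df_resid = fit.df_resid
    tcrit = stats.t.ppf(0.975, df_resid)
    rows = []
    for k, lev in enumerate(levels):
        mean_k = fit.params[k]
        se_k = fit.bse[k]
        rows.append((int(lev), int(ind[:, k].sum()), float(s[q == lev].mean()),
                     float(mean_k), float(mean_k - tcrit * se_k),
                     float(mean_k + tcrit * se_k)))
    table = pd.DataFrame(rows, columns=["quintile", "n", "mean_score",
                                        "adj_bmi", "ci_low", "ci_high"])

    i1 = int(np.searchsorted(levels, levels.min()))
    i5 = int(np.searchsorted(levels, levels.max()))
    contrast = np.zeros(X.shape[1])
    contrast[i5], contrast[i1] = 1.0, -1.0
    diff = float(contrast @ fit.params)
    diff_se = float(np.sqrt(contrast @ fit.cov_params() @ contrast))
    return {"table": table, "q5_minus_q1": diff, "q5_minus_q1_se": diff_se}


def score_bmi_correlation(score: Sequence, bmi: Sequence) -> tuple:
    """Pearson correlation of the integer score with BMI: (r, p)."""
    s = np.asarray(score, dtype=float)
    y = np.asarray(bmi, dtype=float)
    if len(s) < 3:
        raise UndefinedStatisticError("correlation needs at least 3 individuals")
    if np.ptp(s) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant score")
    r, p = stats.pearsonr(s, y)
    return float(r), float(p)


def auc_obesity(score: Sequence, obesity: Sequence) -> float:
    """ROC AUC of the score for obesity, as the Mann-Whitney probability.

    Equals (concordant pairs + 0.5 * tied pairs) / (n_case * n_control),
    computed from midranks.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(obesity, dtype=bool)
    n_case = int(y.sum())
    n_ctrl = int((~y).sum())
    if n_case == 0 or n_ctrl == 0:
        raise UndefinedStatisticError("AUC needs both obese and non-obese individuals")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def incremental_r2(
    score: Sequence,
    bmi: Sequence,
    covariates: pd.DataFrame,
) -> float:
    """Gain in R^2 for BMI from adding the score to the covariate model."""
    y = np.asarray(bmi, dtype=float)
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "female").astype(float)
    base = np.column_stack([np.ones(len(y)), cov.to_numpy(dtype=float)])
    full = np.column_stack([base, np.asarray(score, dtype=float)])
    r2_base = sm.OLS(y, base).fit().rsquared
    r2_full = sm.OLS(y, full).fit().rsquared
    return float(r2_full - r2_base)


def grouped_score_bins(score: Sequence, low: int = 2, high: int = 6) -> pd.Series:
    """Histogram categories with the extremes pooled (<=low and >=high)."""
    s = np.asarray(score)
    labels = np.where(s <= low, f"<={low}", np.where(s >= high, f">={high}",
                                                    s.astype(int).astype(str)))
    order = [f"<={low}"] + [str(v) for v in range(low + 1, high)] + [f">={high}"]
    return pd.Series(pd.Categorical(labels, categories=order, ordered=True))
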