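"""Additive-model SNP association with BMI.

Each SNP is tested by ordinary least squares of BMI (kg/m^2) on the
0/1/2 allele count, adjusted for age and sex (optionally type-2
diabetes, and a cohort indicator in pooled analyses). Complete cases
only: an individual missing the SNP call or any covariate drops out of
that SNP's fit, so the per-SNP N varies with genotyping missingness.
Two-sided p-values come from the t distribution with residual degrees
of freedom. Family-wise error is controlled by Bonferroni over the
number of independent tests in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import GenotypeMatrix, PanelError, SnpPanel, StudyConfig


class DegeneratePredictorError(ValueError):
    """Genotype constant (or covariates collinear) among complete cases."""


@dataclass
class AssocResult:
    """Per-SNP effect of one additive-model fit."""

    snp_id: str
    cohort: str
    effect_allele: str
    other_allele: str
    maf: float
    n: int
    beta: float
    se: float
    t_stat: float
    p: float
    significant_bonferroni: bool = False

    def flipped(self) -> "AssocResult":
        """The same fit reported for the other allele (beta negated)."""
        return AssocResult(
            snp_id=self.snp_id,
            cohort=self.cohort,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            maf=self.maf,
            n=self.n,
            beta=-self.beta,
            se=self.se,
            t_stat=-self.t_stat,
            p=self.p,
            significant_bonferroni=self.significant_bonferroni,
        )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold controlling FWER at ``alpha``."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def _design(covariates: Optional[pd.DataFrame]) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame()
    cov = covariates.copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "female").astype(float)
    for c in cov.columns:
        cov[c] = cov[c].astype(float)
    return cov


def additive_regression(
    bmi: Sequence,
    genotype: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    snp_id: str = "snp",
    cohort: str = "all",
    effect_allele: str = "A",
    other_allele: str = "B",
) -> AssocResult:
    """OLS of BMI on an additive genotype plus covariates, complete cases.

    ``covariates`` may hold ``age`` (years), ``sex`` ("male"/"female" or
    0/1), ``dm2`` and cohort indicators; rows align with ``bmi`` and
    ``genotype``.
    """
    y = np.asarray(bmi, dtype=float)
    g = np.asarray(genotype, dtype=float)
    cov = _design(covariates)
    if len(cov) not in (0, len(y)) or len(g) != len(y):
        raise PanelError("bmi, genotype and covariates must align")

    complete = ~(np.isnan(y) | np.isnan(g))
    if len(cov):
        complete &= ~cov.isna().any(axis=1).to_numpy()
    y, g = y[complete], g[complete]
    X = np.column_stack([np.ones(len(y)), g] +
                        ([cov.loc[complete].to_numpy().T[i] for i in range(cov.shape[1])]
                         if len(cov) else []))
    k = X.shape[1]
    if len(y) < k + 1:
        raise DegeneratePredictorError(
            f"{snp_id}: only {len(y)} complete cases for {k} parameters"
        )
    if np.ptp(g) == 0:
        raise DegeneratePredictorError(f"{snp_id}: genotype constant among complete cases")
    if np.linalg.matrix_rank(X) < k:
        raise DegeneratePredictorError(f"{snp_id}: collinear design matrix")

    fit = sm.OLS(y, X).fit()
    maf = min(g.mean() / 2.0, 1.0 - g.mean() / 2.0)
    return AssocResult(
        snp_id=snp_id,
        cohort=cohort,
        effect_allele=effect_allele,
        other_allele=other_allele,
        maf=float(maf),
        n=int(len(y)),
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t_stat=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
    )


def snp_interaction(
    bmi: Sequence,
    g1: Sequence,
    g2: Sequence,
    covariates: Optional[pd.DataFrame] = None,
) -> dict:
    """Multiplicative SNP x SNP interaction on BMI.

    Fits ``bmi ~ g1 + g2 + g1*g2 + covariates`` and returns the
    product-term estimate together with covariate-adjusted mean BMI for
    each cell of the 3x3 joint-genotype grid (``NaN`` where a cell is
    empty).
    """
    y = np.asarray(bmi, dtype=float)
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    cov = _design(covariates)
    complete = ~(np.isnan(y) | np.isnan(a) | np.isnan(b))
    if len(cov):
        complete &= ~cov.isna().any(axis=1).to_numpy()
    y, a, b = y[complete], a[complete], b[complete]
    cov_arr = cov.loc[complete].to_numpy() if len(cov) else np.empty((len(y), 0))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegeneratePredictorError("both genotypes must vary among complete cases")

    X = np.column_stack([np.ones(len(y)), a, b, a * b, cov_arr])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegeneratePredictorError("interaction term collinear with main effects")
    fit = sm.OLS(y, X).fit()

    cell_means = np.full((3, 3), np.nan)
    cov_mean = cov_arr.mean(axis=0) if cov_arr.shape[1] else np.empty(0)
    coefs = fit.params
    for i in range(3):
        for j in range(3):
            if ((a == i) & (b == j)).any():
                x = np.concatenate([[1.0, i, j, i * j], cov_mean])
                cell_means[i, j] = float(x @ coefs)
    return {
        "beta": float(coefs[3]),
        "se": float(fit.bse[3]),
        "p": float(fit.pvalues[3]),
        "n": int(len(y)),
        "cell_means": cell_means,
    }


def run_panel(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    config: StudyConfig,
    panel: Optional[SnpPanel] = None,
) -> pd.DataFrame:
    """Per-SNP association in each cohort and pooled; one row per fit.

    The pooled fit adds a cohort indicator when
    ``config.pooled_cohort_covariate`` is set; ``config.adjust_dm2``
    adds the diabetes flag everywhere. SNPs whose fit is degenerate in
    an analysis (e.g. monomorphic within one cohort) are skipped there.
    """
    pheno = phenotypes.set_index("individual_id").reindex(gm.individual_ids)
    cohorts = sorted(set(gm.cohort))
    analyses = [(c, np.asarray(gm.cohort) == c) for c in cohorts]
    if len(cohorts) > 1:
        analyses.append(("pooled", np.ones(gm.n_individuals, dtype=bool)))

    threshold = bonferroni_threshold(config.alpha, config.n_independent_tests)
    rows = []
    for name, mask in analyses:
        cov = pd.DataFrame({
            "age": pheno["age"].to_numpy(dtype=float)[mask],
            "sex": (pheno["sex"] == "female").to_numpy(dtype=float)[mask],
        })
        if config.adjust_dm2:
            cov["dm2"] = pheno["dm2"].to_numpy(dtype=float)[mask]
        if name == "pooled" and config.pooled_cohort_covariate:
            for c in cohorts[1:]:
                cov[f"cohort_{c}"] = (np.asarray(gm.cohort)[mask] == c).astype(float)
        bmi = pheno["bmi"].to_numpy(dtype=float)[mask]
        for j, s in enumerate(gm.snp_ids):
            g = gm.counts[mask, j]
            try:
                res = additive_regression(
                    bmi, g, cov,
                    snp_id=s, cohort=name,
                    effect_allele=gm.count_allele[s],
                    other_allele=gm.other_allele[s],
                )
            except DegeneratePredictorError:
                continue
            res.significant_bonferroni = res.p < threshold
            rows.append(res)

    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        df = df.rename(columns={"effect_allele": "a1", "other_allele": "a2"})
    return df
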