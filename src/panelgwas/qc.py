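"""Genotype quality control.

Filters follow standard candidate-gene practice: individuals with a
genotyping call rate below 95% are removed first, then SNPs failing the
call-rate, minor-allele-frequency (< 1%) or Hardy-Weinberg (exact p <
0.001) thresholds, with monomorphic SNPs excluded outright. The HWE test
is the exact conditional test (the sum of probabilities, given the
allele totals, of all heterozygote counts at most as probable as the
observed one), not the asymptotic chi-square.

X-linked SNPs are tested for HWE in females only, since hemizygous
males have no heterozygote class; their allele frequency counts male
genotypes as single-allele draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PanelError, SnpPanel, StudyConfig


class UndefinedStatisticError(ValueError):
    """A statistic was requested on degenerate input (e.g. no calls)."""


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    ``n_hom1``/``n_hom2`` are the two homozygote counts and ``n_het`` the
    heterozygote count. The p-value sums, over every heterozygote count
    compatible with the observed allele totals, the conditional
    probabilities that do not exceed the observed table's probability.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined with no genotypes")
    # work with the rarer allele
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0:
        return 1.0

    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    n_hets = np.arange(het_min, het_max + 1, 2)

    # unnormalized probabilities by recurrence from the smallest het count:
    # P(h+2)/P(h) = 4*hom_rare(h)*hom_common(h) / ((h+2)*(h+1))
    # where hom_rare(h) = (n_rare - h)/2, hom_common(h) = n - h - hom_rare(h).
    logp = np.empty(len(n_hets))
    logp[0] = 0.0
    for k in range(len(n_hets) - 1):
        h = n_hets[k]
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        ratio = 4.0 * hom_rare * hom_common / ((h + 2.0) * (h + 1.0))
        logp[k + 1] = logp[k] + np.log(ratio)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = np.searchsorted(n_hets, n_het)
    if obs >= len(n_hets) or n_hets[obs] != n_het:
        raise ValueError("heterozygote count incompatible with allele totals")
    p_obs = probs[obs]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def genotype_counts(column: np.ndarray) -> tuple:
    """(n copies==2, n copies==1, n copies==0) among non-missing entries."""
    col = column[~np.isnan(column)]
    return int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())


def compute_maf(column: np.ndarray, ploidy: Optional[np.ndarray] = None) -> float:
    """Minor-allele frequency of a genotype column.

    ``ploidy`` (per-individual 1 or 2) supports X-linked SNPs where males
    contribute a single allele; by default all individuals are diploid.
    """
    col = np.asarray(column, dtype=float)
    mask = ~np.isnan(col)
    if not mask.any():
        raise UndefinedStatisticError("MAF undefined: all genotypes missing")
    if ploidy is None:
        total = 2.0 * mask.sum()
    else:
        total = float(np.asarray(ploidy)[mask].sum())
    f = col[mask].sum() / total
    return float(min(f, 1.0 - f))


@dataclass
class QcReport:
    """Per-SNP and per-individual QC statistics and exclusion decisions."""

    snps: pd.DataFrame
    individuals: pd.DataFrame

    @property
    def n_excluded_snps(self) -> int:
        return int((~self.snps["kept"]).sum())

    @property
    def n_excluded_individuals(self) -> int:
        return int((~self.individuals["kept"]).sum())


def _x_info(gm: GenotypeMatrix, phenotypes: pd.DataFrame, panel: Optional[SnpPanel]):
    """Female mask aligned to the matrix rows, and the set of X SNPs."""
    x_snps = set()
    if panel is not None:
        x_snps = {s for s in gm.snp_ids if s in panel and panel[s].is_x}
    sex = phenotypes.set_index("individual_id")["sex"].reindex(gm.individual_ids)
    female = (sex == "female").to_numpy()
    return female, x_snps


def apply_qc(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    config: StudyConfig,
    panel: Optional[SnpPanel] = None,
) -> tuple:
    """Filter individuals then SNPs; return (filtered matrix, QcReport).

    Exclusion reasons, in order of precedence, are ``call_rate``,
    ``monomorphic``, ``maf`` and ``hwe``. ``hwe_p_controls`` is reported
    for the non-obese subset but only the all-individuals p-value
    filters.
    """
    unknown = set(gm.individual_ids) - set(phenotypes["individual_id"])
    if unknown:
        raise PanelError(f"genotyped individuals missing from phenotypes: {sorted(unknown)[:5]}")

    ind_rates = gm.individual_call_rates()
    ind_kept = ind_rates >= config.min_call_rate_individual
    individuals = pd.DataFrame({
        "individual_id": gm.individual_ids,
        "call_rate": ind_rates.to_numpy(),
        "kept": ind_kept.to_numpy(),
        "exclusion_reason": np.where(ind_kept, "", "call_rate"),
    })

    kept_ids = [i for i, k in zip(gm.individual_ids, ind_kept) if k]
    filtered = gm.subset(individuals=kept_ids)
    pheno = phenotypes.set_index("individual_id").reindex(kept_ids)
    female, x_snps = _x_info(filtered, phenotypes, panel)
    non_obese = (~pheno["obesity"].astype(bool)).to_numpy()

    rows = []
    for j, s in enumerate(filtered.snp_ids):
        col = filtered.counts[:, j]
        call_rate = 1.0 - np.isnan(col).mean() if len(col) else 0.0
        is_x = s in x_snps
        if is_x and config.x_male_coding == "0-2":
            # bring hemizygous males back to single-allele counts
            col = np.where(female, col, col / 2.0)
        ploidy = np.where(female, 2, 1) if is_x else None
        try:
            maf = compute_maf(col, ploidy)
        except UndefinedStatisticError:
            maf = np.nan
        hwe_col = col[female] if is_x else col
        ctrl_col = col[female & non_obese] if is_x else col[non_obese]
        hwe_p = _safe_hwe(hwe_col)
        hwe_p_ctrl = _safe_hwe(ctrl_col)

        reason = ""
        if call_rate < config.min_call_rate_snp:
            reason = "call_rate"
        elif np.isnan(maf) or maf == 0.0:
            reason = "monomorphic"
        elif maf < config.min_maf:
            reason = "maf"
        elif not np.isnan(hwe_p) and hwe_p < config.min_hwe_p:
            reason = "hwe"
        rows.append((s, call_rate, maf, hwe_p, hwe_p_ctrl, reason == "", reason))

    snps = pd.DataFrame(
        rows,
        columns=["snp_id", "call_rate", "maf", "hwe_p", "hwe_p_controls",
                 "kept", "exclusion_reason"],
    )
    kept_snps = list(snps.loc[snps["kept"], "snp_id"])
    return filtered.subset(snps=kept_snps), QcReport(snps=snps, individuals=individuals)


def _safe_hwe(col: np.ndarray) -> float:
    hom2, het, hom0 = genotype_counts(col)
    if hom2 + het + hom0 == 0:
        return np.nan
    return hwe_exact_test(hom2, het, hom0)
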