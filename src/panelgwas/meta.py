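"""Two-cohort meta-analysis of per-SNP effects.

Effects are pooled per SNP by inverse-variance fixed-effect weighting
and by the DerSimonian-Laird random-effects model, after harmonizing the
effect alleles across cohorts. Heterogeneity is summarized by Cochran's
Q (chi-square with k-1 df) and the I^2 index, 100*(Q-df)/Q truncated at
zero. When Q <= df the between-study variance estimate tau^2 is zero and
the random-effects output coincides with the fixed-effect one.

Allele harmonization: identical effect alleles pass through; effect
alleles swapped within the SNP's known allele pair flip the second
study's sign — unless the pair is strand-ambiguous (A/T or C/G), which
cannot be distinguished from a strand flip and is excluded; alleles not
forming the known pair are excluded as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssocResult
from .types import SnpRecord


@dataclass
class MetaResult:
    """Pooled effect and heterogeneity statistics for one SNP."""

    snp_id: str
    effect_allele: str
    beta_fe: float = np.nan
    se_fe: float = np.nan
    p_fe: float = np.nan
    beta_re: float = np.nan
    se_re: float = np.nan
    p_re: float = np.nan
    tau2: float = np.nan
    q: float = np.nan
    df: int = 0
    p_q: float = np.nan
    i2: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""


def align_alleles(
    result_1: AssocResult,
    result_2: AssocResult,
    record: SnpRecord,
) -> tuple:
    """Harmonize two cohort results to a shared effect allele.

    Returns ``(r1, r2, reason)`` where ``reason`` is "" on success,
    or ``"allele_mismatch"`` / ``"ambiguous_strand"`` when the pair must
    be excluded (then the results are returned unchanged).
    """
    if result_1.snp_id != result_2.snp_id:
        raise ValueError("align_alleles requires results for the same SNP")
    a1, a2 = result_1.effect_allele, result_2.effect_allele
    if a1 == a2:
        return result_1, result_2, ""
    if {a1, a2} == set(record.alleles):
        if record.strand_ambiguous:
            return result_1, result_2, "ambiguous_strand"
        return result_1, result_2.flipped(), ""
    return result_1, result_2, "allele_mismatch"


def fixed_effect_meta(betas: Sequence, ses: Sequence) -> tuple:
    """Inverse-variance fixed-effect pooling: (beta, se, z, p)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("meta-analysis needs at least two studies")
    if (s <= 0).any():
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, float(z), float(p)


def cochran_q_i2(betas: Sequence, ses: Sequence) -> tuple:
    """Cochran's Q heterogeneity test and I^2: (q, df, p_q, i2_percent)."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if len(b) < 2:
        raise ValueError("heterogeneity needs at least two studies")
    w = 1.0 / s**2
    beta_fe = (w * b).sum() / w.sum()
    q = float((w * (b - beta_fe) ** 2).sum())
    df = len(b) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return q, df, p_q, float(i2)


def dersimonian_laird(betas: Sequence, ses: Sequence) -> tuple:
    """DerSimonian-Laird random-effects pooling: (tau2, beta, se, p).

    tau^2 is the moment estimate max(0, (Q - df) / (S1 - S2/S1)) with
    S1 = sum of fixed weights and S2 = sum of squared fixed weights;
    study weights become 1/(se^2 + tau^2).
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    q, df, _, _ = cochran_q_i2(b, s)
    w = 1.0 / s**2
    s1 = w.sum()
    s2 = (w**2).sum()
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    w_star = 1.0 / (s**2 + tau2)
    beta = float((w_star * b).sum() / w_star.sum())
    se = float(w_star.sum() ** -0.5)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return float(tau2), beta, se, float(p)


def meta_analyze_snp(
    result_1: AssocResult,
    result_2: AssocResult,
    record: SnpRecord,
) -> MetaResult:
    """Harmonize and pool one SNP's two cohort results."""
    r1, r2, reason = align_alleles(result_1, result_2, record)
    if reason:
        return MetaResult(snp_id=record.snp_id, effect_allele=result_1.effect_allele,
                          excluded=True, exclusion_reason=reason)
    betas = [r1.beta, r2.beta]
    ses = [r1.se, r2.se]
    beta_fe, se_fe, _, p_fe = fixed_effect_meta(betas, ses)
    q, df, p_q, i2 = cochran_q_i2(betas, ses)
    tau2, beta_re, se_re, p_re = dersimonian_laird(betas, ses)
    return MetaResult(
        snp_id=record.snp_id,
        effect_allele=r1.effect_allele,
        beta_fe=beta_fe, se_fe=se_fe, p_fe=p_fe,
        beta_re=beta_re, se_re=se_re, p_re=p_re,
        tau2=tau2, q=q, df=df, p_q=p_q, i2=i2,
    )


def meta_analyze_table(
    assoc: pd.DataFrame,
    panel,
    cohorts: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Meta-analyze a long association table with two cohorts per SNP.

    ``assoc`` needs columns ``snp_id, cohort, a1, a2, beta, se`` (the
    layout produced by :func:`panelgwas.assoc.run_panel` or the bundled
    published table). Pooled-analysis rows are ignored. Returns one row
    per SNP, including excluded ones with their reason.
    """
    df = assoc[~assoc["cohort"].str.lower().isin(["pooled"])].copy()
    if cohorts is None:
        cohorts = sorted(df["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError(f"exactly two cohorts required, got {list(cohorts)}")

    rows = []
    for snp_id, grp in df.groupby("snp_id", sort=False):
        grp = grp.set_index("cohort")
        if not all(c in grp.index for c in cohorts):
            continue
        results = []
        for c in cohorts:
            r = grp.loc[c]
            results.append(AssocResult(
                snp_id=snp_id, cohort=c,
                effect_allele=r["a1"], other_allele=r["a2"],
                maf=float(r.get("maf", np.nan)), n=int(r.get("n", 0)),
                beta=float(r["beta"]), se=float(r["se"]),
                t_stat=float(r["beta"]) / float(r["se"]),
                p=float(r.get("p", np.nan)),
            ))
        rows.append(meta_analyze_snp(results[0], results[1], panel[snp_id]))
    return pd.DataFrame([r.__dict__ for r in rows])
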