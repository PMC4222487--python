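"""Synthetic two-cohort genotype and phenotype generator.

The generator reproduces the statistical structure the downstream
analysis assumes: genotypes are two independent allele draws per SNP
(Hardy-Weinberg proportions) or two haplotype draws from an LD pool;
BMI is a linear additive trait,

    BMI_i = intercept + age_beta * age_i + sex_beta * [female_i]
            + sum_j beta_j * g_ij + Normal(0, bmi_sd),

with missing calls applied completely at random after phenotypes are
generated, so complete-case sample sizes vary per SNP exactly as in
real panel data. X-linked SNPs give males a single allele draw, stored
as 0/1 (or 0/2 on request).

Ready-made configurations calibrate the two cohorts to the published
study conditions: the rural cohort ("PIZARRA", n=869, BMI 28.6 +/- 5.2,
63% female, age 46 +/- 14) and the urban cohort ("HORTEGA", n=1425,
BMI 26.4 +/- 4.2, 50% female, age 54 +/- 19), with per-SNP allele
frequencies, per-allele effect sizes and call rates taken from the
bundled published tables. The intercept and residual SD are derived
from the target BMI mean and SD, so the marginal BMI distribution
matches the targets once the (small) genetic and covariate
contributions are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import tables
from .types import GenotypeMatrix, PanelError, validate_phenotypes


class LdFeasibilityError(ValueError):
    """A requested r^2 exceeds what the allele frequencies allow."""


@dataclass
class HaplotypePool:
    """A haplotype spectrum over a SNP block: vectors with frequencies.

    ``haplotypes`` is an H x k 0/1 array where 1 denotes the counted
    (a1) allele at that site.
    """

    snp_ids: list
    haplotypes: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=int)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise PanelError("haplotype pool frequencies must sum to 1")

    def allele_freqs(self) -> np.ndarray:
        return self.freqs @ self.haplotypes

    def pairwise_r2(self) -> np.ndarray:
        p = self.allele_freqs()
        k = len(p)
        r2 = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                p11 = self.freqs[(self.haplotypes[:, i] == 1)
                                 & (self.haplotypes[:, j] == 1)].sum()
                d = p11 - p[i] * p[j]
                denom = p[i] * (1 - p[i]) * p[j] * (1 - p[j])
                r2[i, j] = r2[j, i] = d * d / denom
        return r2


def max_r2(p_a: float, p_b: float) -> float:
    """Largest attainable r^2 for positively associated alleles."""
    d_max = min(p_a * (1 - p_b), p_b * (1 - p_a))
    return d_max**2 / (p_a * (1 - p_a) * p_b * (1 - p_b))


def _pair_pool(p_a: float, p_b: float, r2: float) -> np.ndarray:
    """Exact 2-SNP haplotype frequencies (11, 10, 01, 00) for target r^2."""
    d = np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))
    return np.array([
        p_a * p_b + d,
        p_a * (1 - p_b) - d,
        (1 - p_a) * p_b - d,
        (1 - p_a) * (1 - p_b) + d,
    ])


def _latent_rho(p_a: float, p_b: float, r2: float) -> float:
    """Gaussian-copula correlation reproducing a pairwise target r^2."""
    if r2 == 0.0:
        return 0.0
    za, zb = stats.norm.ppf([p_a, p_b])
    target_p11 = p_a * p_b + np.sqrt(r2 * p_a * (1 - p_a) * p_b * (1 - p_b))

    def gap(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        return stats.multivariate_normal(mean=[0, 0], cov=cov,
                                         allow_singular=True).cdf([za, zb]) - target_p11

    return float(optimize.brentq(gap, 0.0, 1.0 - 1e-12, xtol=1e-12))


def simulate_haplotype_pool(
    target_freqs: Sequence,
    target_r2,
    tol: float = 0.02,
) -> HaplotypePool:
    """Construct a haplotype pool with given allele freqs and pairwise r^2.

    ``target_r2`` is a scalar applied to every pair, or a full symmetric
    matrix. All associations are taken positive (risk alleles travel
    together). Two SNPs are solved exactly; larger blocks use a
    Gaussian-copula (latent multivariate normal threshold) construction
    whose haplotype probabilities are orthant probabilities, and the
    realized pairwise r^2 is verified to be within ``tol`` of the target.
    Raises :class:`LdFeasibilityError`, naming the attainable bound, if
    a target exceeds it.
    """
    p = np.asarray(target_freqs, dtype=float)
    k = len(p)
    if ((p <= 0) | (p >= 1)).any():
        raise PanelError("allele frequencies must lie strictly inside (0, 1)")
    r2 = np.asarray(target_r2, dtype=float)
    if r2.ndim == 0:
        r2 = np.full((k, k), float(r2))
        np.fill_diagonal(r2, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            bound = max_r2(p[i], p[j])
            if r2[i, j] > bound + 1e-12:
                raise LdFeasibilityError(
                    f"target r^2={r2[i, j]:.4g} for freqs ({p[i]:.3g}, {p[j]:.3g}) "
                    f"exceeds the attainable bound {bound:.4g}"
                )
    snp_ids = [f"snp{j}" for j in range(k)]

    if k == 1:
        return HaplotypePool(snp_ids, np.array([[1], [0]]), np.array([p[0], 1 - p[0]]))
    if k == 2:
        freqs = _pair_pool(p[0], p[1], r2[0, 1])
        haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        keep = freqs > 1e-12
        return HaplotypePool(snp_ids, haps[keep], freqs[keep] / freqs[keep].sum())

    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            rho[i, j] = rho[j, i] = _latent_rho(p[i], p[j], r2[i, j])
    if np.linalg.eigvalsh(rho).min() < -1e-8:
        raise LdFeasibilityError(
            "pairwise r^2 targets are jointly infeasible "
            "(latent correlation matrix is not positive semidefinite)"
        )
    z = stats.norm.ppf(p)
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=rho, allow_singular=True)
    haps = np.array(np.meshgrid(*[[1, 0]] * k, indexing="ij")).reshape(k, -1).T
    freqs = np.empty(len(haps))
    big = 12.0
    for h_idx, h in enumerate(haps):
        lower = np.where(h == 1, -big, z)
        upper = np.where(h == 1, z, big)
        freqs[h_idx] = mvn.cdf(upper, lower_limit=lower)
    freqs = np.clip(freqs, 0.0, None)
    freqs /= freqs.sum()
    pool = HaplotypePool(snp_ids, haps, freqs)

    realized = pool.pairwise_r2()
    off = ~np.eye(k, dtype=bool)
    if np.abs(realized[off] - r2[off]).max() > tol:
        raise LdFeasibilityError(
            "copula construction missed a pairwise r^2 target by more than "
            f"{tol}; targets are jointly infeasible"
        )
    return pool


@dataclass
class CohortSimConfig:
    """Generative parameters for one synthetic cohort.

    ``snps`` holds one row per marker: ``snp_id, gene, chromosome,
    position, a1, a2, maf, beta, miss_rate``; ``maf`` is the a1
    frequency, ``beta`` the BMI shift (kg/m^2) per a1 copy and
    ``miss_rate`` the per-SNP missing-call probability. ``ld_blocks``
    lists haplotype pools over disjoint subsets of these SNPs; SNPs in
    no block are drawn independently under Hardy-Weinberg.
    """

    name: str
    n: int
    snps: pd.DataFrame
    bmi_intercept: float
    bmi_sd: float
    age_mean: float
    age_sd: float
    female_fraction: float
    age_beta: float = 0.0
    sex_beta: float = 0.0
    dm2_prevalence: float = 0.1
    miss_rate_ind: float = 0.0
    ld_blocks: list = field(default_factory=list)
    age_range: tuple = (18.0, 90.0)
    x_male_coding: str = "0-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PanelError("cohort size must be >= 1")
        if ((self.snps["maf"] <= 0) | (self.snps["maf"] > 0.5)).any():
            raise PanelError("SNP maf values must lie in (0, 0.5]")
        if self.bmi_sd <= 0:
            raise PanelError("bmi_sd must be positive")
        in_blocks = [s for b in self.ld_blocks for s in b.snp_ids]
        if len(in_blocks) != len(set(in_blocks)):
            raise PanelError("a SNP may belong to at most one LD block")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(config: CohortSimConfig) -> tuple:
    """Simulate one cohort; returns ``(GenotypeMatrix, phenotype frame)``."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    snps = config.snps.reset_index(drop=True)
    snp_ids = list(snps["snp_id"])
    ids = [f"{config.name}_{i:05d}" for i in range(n)]

    female = rng.random(n) < config.female_fraction
    age = _truncnorm(rng, config.age_mean, config.age_sd, *config.age_range, size=n)
    dm2 = rng.random(n) < config.dm2_prevalence

    counts = np.empty((n, len(snp_ids)))
    in_block = set()
    col_of = {s: j for j, s in enumerate(snp_ids)}
    for pool in config.ld_blocks:
        hap_idx = rng.choice(len(pool.freqs), size=(n, 2), p=pool.freqs)
        geno = pool.haplotypes[hap_idx[:, 0]] + pool.haplotypes[hap_idx[:, 1]]
        for b_j, s in enumerate(pool.snp_ids):
            counts[:, col_of[s]] = geno[:, b_j]
            in_block.add(s)
    for j, row in snps.iterrows():
        if row.snp_id in in_block:
            continue
        p = float(row.maf)
        if str(row.chromosome).upper() == "X":
            g = np.where(female,
                         rng.binomial(2, p, size=n),
                         rng.binomial(1, p, size=n))
            if config.x_male_coding == "0-2":
                g = np.where(female, g, 2 * g)
            counts[:, j] = g
        else:
            counts[:, j] = rng.binomial(2, p, size=n)

    betas = snps["beta"].to_numpy(dtype=float)
    bmi = (config.bmi_intercept
           + config.age_beta * age
           + config.sex_beta * female
           + counts @ betas
           + rng.normal(0.0, config.bmi_sd, size=n))

    # missingness is applied after the phenotype: MCAR per entry
    miss_snp = snps["miss_rate"].to_numpy(dtype=float)
    p_miss = 1.0 - (1.0 - miss_snp[None, :]) * (1.0 - config.miss_rate_ind)
    counts[rng.random(counts.shape) < p_miss] = np.nan

    gm = GenotypeMatrix(
        individual_ids=ids,
        snp_ids=snp_ids,
        counts=counts,
        count_allele=dict(zip(snp_ids, snps["a1"])),
        other_allele=dict(zip(snp_ids, snps["a2"])),
        cohort=np.array([config.name] * n, dtype=object),
    )
    pheno = validate_phenotypes(pd.DataFrame({
        "individual_id": ids,
        "cohort": config.name,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "bmi": bmi,
        "dm2": dm2,
    }))
    return gm, pheno


# ---------------------------------------------------------------------------
# calibrated study conditions

#: Cohort-level targets: n, BMI mean/SD, age mean/SD, female fraction,
#: type-2-diabetes prevalence.
COHORT_TARGETS = {
    "PIZARRA": dict(n=869, bmi_mean=28.6, bmi_sd=5.2, age_mean=46.2,
                    age_sd=13.8, female_fraction=0.628, dm2_prevalence=0.189),
    "HORTEGA": dict(n=1425, bmi_mean=26.4, bmi_sd=4.2, age_mean=54.4,
                    age_sd=19.3, female_fraction=0.496, dm2_prevalence=0.077),
}

#: Default covariate effects on BMI (kg/m^2 per year; kg/m^2 for female
#: sex). The source study reports no such effect sizes, so these are
#: generator conventions of plausible magnitude.
DEFAULT_AGE_BETA = 0.04
DEFAULT_SEX_BETA = 0.8


def _snp_table(cohort: str, effect_scale: float = 1.0,
               null_effects: bool = False) -> pd.DataFrame:
    panel = tables.load_panel_frame().set_index("snp_id")
    assoc = tables.load_tagsnp_assoc()
    sub = assoc[assoc["cohort"] == cohort].set_index("snp_id")
    rows = []
    callrate_col = f"callrate_{cohort.lower()}"
    for snp_id, r in sub.iterrows():
        pan = panel.loc[snp_id]
        beta = 0.0 if null_effects else effect_scale * float(r["beta"])
        rows.append(dict(
            snp_id=snp_id, gene=r["gene"], chromosome=pan["chromosome"],
            position=int(pan["position"]),
            a1=pan["allele_a1"], a2=pan["allele_a2"],
            maf=min(float(r["maf"]), 1.0 - float(r["maf"])),
            beta=beta,
            miss_rate=max(0.0, 1.0 - float(pan[callrate_col]) / 100.0),
        ))
    return pd.DataFrame(rows)


def _genetic_moments(snps: pd.DataFrame, female_fraction: float,
                     x_male_coding: str) -> tuple:
    """Mean and variance of the total genetic BMI contribution."""
    mean = var = 0.0
    for r in snps.itertuples():
        p, b = r.maf, r.beta
        if str(r.chromosome).upper() == "X":
            male_dose = p if x_male_coding == "0-1" else 2 * p
            male_var = p * (1 - p) * (1 if x_male_coding == "0-1" else 4)
            mu_f, mu_m = 2 * p, male_dose
            ff = female_fraction
            mu = ff * mu_f + (1 - ff) * mu_m
            v = (ff * 2 * p * (1 - p) + (1 - ff) * male_var
                 + ff * (1 - ff) * (mu_f - mu_m) ** 2)
        else:
            mu = 2 * p
            v = 2 * p * (1 - p)
        mean += b * mu
        var += b * b * v
    return mean, var


def cohort_config(
    cohort: str,
    seed: int = 0,
    effect_scale: float = 1.0,
    null_effects: bool = False,
    beta_override: Optional[dict] = None,
    ld_blocks: Optional[list] = None,
    x_male_coding: str = "0-1",
) -> CohortSimConfig:
    """A :class:`CohortSimConfig` calibrated to one study cohort.

    ``cohort`` is "PIZARRA" or "HORTEGA". The per-SNP allele
    frequencies, effect sizes and missing rates come from the bundled
    published tables; the intercept and residual SD are solved so that
    the marginal BMI mean and SD match the cohort targets after adding
    the covariate and genetic contributions. ``null_effects=True`` sets
    every genetic effect to zero (for calibration studies);
    ``effect_scale`` scales all effects jointly; ``beta_override`` maps
    snp_id to an effect replacing the cohort's own (SNPs absent from
    the mapping keep theirs, or zero under ``null_effects``).
    """
    if cohort not in COHORT_TARGETS:
        raise PanelError(f"unknown cohort {cohort!r}; use one of {sorted(COHORT_TARGETS)}")
    t = COHORT_TARGETS[cohort]
    snps = _snp_table(cohort, effect_scale=effect_scale, null_effects=null_effects)
    if beta_override:
        snps["beta"] = [float(beta_override.get(s, b))
                        for s, b in zip(snps["snp_id"], snps["beta"])]

    lo, hi = 18.0, 90.0
    a, b = (lo - t["age_mean"]) / t["age_sd"], (hi - t["age_mean"]) / t["age_sd"]
    age_mu, age_var = stats.truncnorm.stats(a, b, loc=t["age_mean"],
                                            scale=t["age_sd"], moments="mv")
    g_mean, g_var = _genetic_moments(snps, t["female_fraction"], x_male_coding)
    ff = t["female_fraction"]
    intercept = (t["bmi_mean"] - DEFAULT_AGE_BETA * float(age_mu)
                 - DEFAULT_SEX_BETA * ff - g_mean)
    resid_var = (t["bmi_sd"] ** 2
                 - DEFAULT_AGE_BETA**2 * float(age_var)
                 - DEFAULT_SEX_BETA**2 * ff * (1 - ff)
                 - g_var)
    resid_sd = float(np.sqrt(max(resid_var, 0.25)))

    return CohortSimConfig(
        name=cohort,
        n=t["n"],
        snps=snps,
        bmi_intercept=float(intercept),
        bmi_sd=resid_sd,
        age_mean=t["age_mean"],
        age_sd=t["age_sd"],
        female_fraction=ff,
        age_beta=DEFAULT_AGE_BETA,
        sex_beta=DEFAULT_SEX_BETA,
        dm2_prevalence=t["dm2_prevalence"],
        ld_blocks=ld_blocks or [],
        x_male_coding=x_male_coding,
        seed=seed,
    )


def generate_two_cohort_study(
    seed: int = 0,
    effect_scale: float = 1.0,
    null_effects: bool = False,
    beta_override: Optional[dict] = None,
) -> tuple:
    """Simulate both cohorts and stack them; returns (gm, phenotypes).

    Cohort seeds are derived from ``seed`` so the two samples are
    independent but jointly reproducible. ``beta_override`` applies the
    same per-SNP effects to both cohorts (useful for studies generated
    under the pooled effect sizes).
    """
    parts = []
    for k, cohort in enumerate(tables.COHORTS):
        cfg = cohort_config(cohort, seed=(seed * 1000003 + k) % (2**31 - 1),
                            effect_scale=effect_scale, null_effects=null_effects,
                            beta_override=beta_override)
        parts.append(generate_cohort(cfg))
    gms, phenos = zip(*parts)
    gm0 = gms[0]
    combined = GenotypeMatrix(
        individual_ids=[i for g in gms for i in g.individual_ids],
        snp_ids=list(gm0.snp_ids),
        counts=np.vstack([g.counts for g in gms]),
        count_allele=gm0.count_allele,
        other_allele=gm0.other_allele,
        cohort=np.concatenate([g.cohort for g in gms]),
    )
    pheno = pd.concat(phenos, ignore_index=True)
    return combined, pheno
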