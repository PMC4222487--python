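"""Independent brute-force oracles used by the test suite.

Each function recomputes a statistic by the most direct route available
(full enumeration, normal equations, rational arithmetic), deliberately
avoiding the code paths of the package implementation.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as t_dist


def hwe_enumeration(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE p by direct enumeration of all heterozygote counts.

    Uses the closed-form conditional probability of each table given the
    allele totals, via log-factorials.
    """
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele copies
    n_b = 2 * n - n_a

    def log_prob(het):
        hom_rare = (n_a - het) // 2
        hom_common = n - het - hom_rare
        return (gammaln(n + 1) - gammaln(hom_rare + 1) - gammaln(het + 1)
                - gammaln(hom_common + 1) + het * np.log(2)
                + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))

    hets = range(n_a % 2, min(n_a, n_b) + 1, 2)
    probs = {h: np.exp(log_prob(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(1.0, sum(p for p in probs.values() if p / total <= p_obs * (1 + 1e-12)) / total)


def ols_normal_equations(y, X):
    """(beta, se, t, p) for each coefficient via explicit normal equations."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    p = 2 * t_dist.sf(np.abs(t), df)
    return beta, se, t, p


def dl_meta_rational(betas, ses):
    """DerSimonian-Laird pooling in exact rational arithmetic.

    Returns (tau2, beta_re, se_re) with tau2/beta_re computed over
    Fractions and only the final square root in floating point.
    """
    b = [Fraction(x).limit_denominator(10**12) for x in betas]
    v = [Fraction(s).limit_denominator(10**12) ** 2 for s in ses]
    w = [1 / vi for vi in v]
    s1 = sum(w)
    beta_fe = sum(wi * bi for wi, bi in zip(w, b)) / s1
    q = sum(wi * (bi - beta_fe) ** 2 for wi, bi in zip(w, b))
    df = len(b) - 1
    tau2 = max(Fraction(0), (q - df) / (s1 - sum(wi**2 for wi in w) / s1))
    w_star = [1 / (vi + tau2) for vi in v]
    beta_re = sum(wi * bi for wi, bi in zip(w_star, b)) / sum(w_star)
    se_re = float(sum(w_star)) ** -0.5
    return float(tau2), float(beta_re), se_re


def auc_pair_enumeration(score, labels):
    """AUC as (concordant + 0.5 * tied) case-control pairs, enumerated."""
    score = np.asarray(score, float)
    labels = np.asarray(labels, bool)
    cases = score[labels]
    controls = score[~labels]
    total = 0.0
    for c in cases:
        for u in controls:
            total += 1.0 if c > u else (0.5 if c == u else 0.0)
    return total / (len(cases) * len(controls))


def two_snp_loglik_grid(genotype_counts, step=0.01):
    """Maximum log-likelihood over a grid on the 4-haplotype simplex.

    ``genotype_counts`` is a 3x3 array: counts of individuals with
    (g1, g2) copies of the counted alleles. Haplotype order is
    (11, 10, 01, 00).
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    f11, f10, f01 = np.meshgrid(grid, grid, grid, indexing="ij")
    f00 = 1.0 - f11 - f10 - f01
    ok = f00 >= -1e-12
    f11, f10, f01, f00 = (a[ok] for a in (f11, f10, f01, f00))
    f00 = np.clip(f00, 0.0, None)

    pattern_probs = {
        (0, 0): f00**2,
        (0, 1): 2 * f00 * f01,
        (0, 2): f01**2,
        (1, 0): 2 * f10 * f00,
        (1, 1): 2 * f11 * f00 + 2 * f10 * f01,
        (1, 2): 2 * f01 * f11,
        (2, 0): f10**2,
        (2, 1): 2 * f11 * f10,
        (2, 2): f11**2,
    }
    with np.errstate(divide="ignore"):
        ll = np.zeros(f11.shape)
        for (g1, g2), prob in pattern_probs.items():
            c = genotype_counts[g1, g2]
            if c:
                ll = ll + c * np.log(prob)
    return float(np.nanmax(ll[np.isfinite(ll)]))


def min_tag_cover(covers):
    """Smallest tag set covering all SNPs, by exhaustive subset search.

    ``covers`` is a boolean matrix: covers[i, j] iff SNP i tags SNP j.
    """
    m = covers.shape[0]
    for k in range(1, m + 1):
        for subset in combinations(range(m), k):
            if covers[list(subset)].any(axis=0).all():
                return k
    return m
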