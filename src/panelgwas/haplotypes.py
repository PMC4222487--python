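"""Haplotype-frequency estimation, LD and tagging from unphased genotypes.

Haplotype frequencies over small marker blocks (at most 8 SNPs, i.e. 256
possible haplotypes) are estimated by expectation-maximization: the
E-step distributes each individual's unphased genotype over all
compatible ordered haplotype pairs in proportion to the current
frequency products, and the M-step re-estimates frequencies from the
expected haplotype counts. Missing sites within a block enlarge the
compatible set rather than dropping the individual. Pairwise linkage
disequilibrium is reported as r^2 = D^2 / (pA (1-pA) pB (1-pB)) with D
taken from the two-SNP EM solution. Blocks are maximal runs of
position-consecutive SNPs with all pairwise r^2 at or above a threshold
(0.8 by default), and tag SNPs are chosen greedily by coverage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assoc import additive_regression
from .qc import UndefinedStatisticError
from .types import GenotypeMatrix

MAX_BLOCK_SNPS = 8

# per-site compatible ordered allele pairs, keyed by genotype value
_SITE_PAIRS = {
    0.0: ((0, 0),),
    1.0: ((0, 1), (1, 0)),
    2.0: ((1, 1),),
    -1.0: ((0, 0), (0, 1), (1, 0), (1, 1)),  # missing
}


@dataclass
class HaplotypeBlock:
    """EM-estimated haplotype spectrum of one SNP block."""

    snp_ids: list
    haplotypes: list          # allele-letter strings, one char per SNP
    freqs: np.ndarray
    dosage: np.ndarray        # individuals x haplotypes expected copies
    individual_ids: list
    log_likelihood: float
    n_iter: int
    converged: bool
    n_dropped: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"haplotype": self.haplotypes, "freq": self.freqs})


def _compatible_pairs(pattern: tuple, k: int):
    """All ordered haplotype-index pairs compatible with one genotype pattern."""
    options = [_SITE_PAIRS[v] for v in pattern]
    pairs = []
    for combo in itertools.product(*options):
        h1 = h2 = 0
        for a, b in combo:
            h1 = (h1 << 1) | a
            h2 = (h2 << 1) | b
        pairs.append((h1, h2))
    return pairs


def em_haplotype_frequencies(
    genotypes,
    snp_ids: Optional[Sequence] = None,
    individual_ids: Optional[Sequence] = None,
    allele_labels: Optional[Sequence] = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    max_missing_frac: float = 0.5,
) -> HaplotypeBlock:
    """Estimate haplotype frequencies for a block of <= 8 SNPs.

    ``genotypes`` is either a :class:`GenotypeMatrix` (with ``snp_ids``
    selecting the block) or an individuals x SNPs array of 0/1/2 counts
    with ``NaN`` missing. Individuals missing more than half the block
    are dropped (counted in ``n_dropped``). Starting from the uniform
    distribution over haplotypes seen in at least one compatible pair,
    iteration stops when the L1 change in frequencies falls below
    ``tol``; non-convergence sets ``converged=False`` rather than
    raising. The log-likelihood is checked to be non-decreasing at every
    iteration.
    """
    if isinstance(genotypes, GenotypeMatrix):
        gm = genotypes
        ids = list(snp_ids) if snp_ids is not None else list(gm.snp_ids)
        arr = np.column_stack([gm.column(s) for s in ids])
        individual_ids = list(gm.individual_ids)
        allele_labels = [(gm.count_allele[s], gm.other_allele[s]) for s in ids]
    else:
        arr = np.asarray(genotypes, dtype=float)
        ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(arr.shape[1])]
    k = arr.shape[1]
    if k > MAX_BLOCK_SNPS:
        raise ValueError(f"block of {k} SNPs exceeds the {MAX_BLOCK_SNPS}-SNP limit")
    if individual_ids is None:
        individual_ids = [f"ind{i}" for i in range(arr.shape[0])]
    if allele_labels is None:
        allele_labels = [("1", "0")] * k

    miss_frac = np.isnan(arr).mean(axis=1)
    keep = miss_frac <= max_missing_frac
    n_dropped = int((~keep).sum())
    arr = arr[keep]
    kept_ids = [i for i, f in zip(individual_ids, keep) if f]
    n = arr.shape[0]
    if n == 0:
        raise UndefinedStatisticError("no individuals with usable genotypes in block")

    coded = np.where(np.isnan(arr), -1.0, arr)
    patterns, inverse, counts = np.unique(coded, axis=0, return_inverse=True,
                                          return_counts=True)
    pair_sets = [_compatible_pairs(tuple(p), k) for p in patterns]

    n_hap = 1 << k
    seen = np.zeros(n_hap, dtype=bool)
    for pairs in pair_sets:
        for h1, h2 in pairs:
            seen[h1] = seen[h2] = True
    freqs = np.where(seen, 1.0 / seen.sum(), 0.0)

    loglik = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        expected = np.zeros(n_hap)
        new_loglik = 0.0
        for pairs, w in zip(pair_sets, counts):
            probs = np.array([freqs[h1] * freqs[h2] for h1, h2 in pairs])
            total = probs.sum()
            if total <= 0:
                continue
            new_loglik += w * np.log(total)
            probs /= total
            for (h1, h2), p in zip(pairs, probs):
                expected[h1] += w * p
                expected[h2] += w * p
        new_freqs = expected / (2.0 * n)
        assert new_loglik >= loglik - 1e-9 * max(1.0, abs(loglik)), \
            "EM log-likelihood decreased"
        delta = np.abs(new_freqs - freqs).sum()
        freqs, loglik = new_freqs, new_loglik
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("haplotype EM did not converge; results carry converged=False")

    # posterior-expected haplotype copies per individual
    dosage_by_pattern = np.zeros((len(patterns), n_hap))
    for idx, pairs in enumerate(pair_sets):
        probs = np.array([freqs[h1] * freqs[h2] for h1, h2 in pairs])
        total = probs.sum()
        if total <= 0:
            continue
        probs /= total
        for (h1, h2), p in zip(pairs, probs):
            dosage_by_pattern[idx, h1] += p
            dosage_by_pattern[idx, h2] += p
    dosage_full = dosage_by_pattern[inverse]

    keep_h = np.flatnonzero(freqs > 0)
    labels = []
    for h in keep_h:
        bits = [(h >> (k - 1 - j)) & 1 for j in range(k)]
        labels.append("".join(allele_labels[j][0] if b else allele_labels[j][1]
                              for j, b in enumerate(bits)))
    return HaplotypeBlock(
        snp_ids=ids,
        haplotypes=labels,
        freqs=freqs[keep_h],
        dosage=dosage_full[:, keep_h],
        individual_ids=kept_ids,
        log_likelihood=float(loglik),
        n_iter=n_iter,
        converged=converged,
        n_dropped=n_dropped,
    )


def ld_r2(g1: Sequence, g2: Sequence) -> float:
    """Squared allelic correlation between two SNPs, via two-SNP EM.

    Computed on shared complete cases; both SNPs must be polymorphic
    there.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) == 0:
        raise UndefinedStatisticError("no shared complete cases")
    pa = a.mean() / 2.0
    pb = b.mean() / 2.0
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise UndefinedStatisticError("r^2 undefined for a monomorphic SNP")
    block = em_haplotype_frequencies(np.column_stack([a, b]))
    # haplotype label order: bit 1 = count allele ("1"), bit 0 = "0"
    p11 = 0.0
    p1_ = 0.0
    p_1 = 0.0
    for lab, f in zip(block.haplotypes, block.freqs):
        if lab[0] == "1":
            p1_ += f
        if lab[1] == "1":
            p_1 += f
        if lab == "11":
            p11 = f
    d = p11 - p1_ * p_1
    denom = p1_ * (1 - p1_) * p_1 * (1 - p_1)
    return float(d * d / denom)


def ld_matrix(gm: GenotypeMatrix, snp_ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Symmetric pairwise r^2 matrix (diagonal 1) over the given SNPs."""
    ids = list(snp_ids) if snp_ids is not None else list(gm.snp_ids)
    r2 = np.eye(len(ids))
    for i, j in itertools.combinations(range(len(ids)), 2):
        r2[i, j] = r2[j, i] = ld_r2(gm.column(ids[i]), gm.column(ids[j]))
    return pd.DataFrame(r2, index=ids, columns=ids)


def find_blocks_and_tags(ld: pd.DataFrame, r2_threshold: float = 0.8) -> tuple:
    """LD blocks and a greedy tag set from an ordered r^2 matrix.

    ``ld`` rows/columns must already be ordered by chromosomal position.
    Blocks are maximal runs of consecutive SNPs whose *all* pairwise r^2
    meet the threshold. Tags are chosen greedily: repeatedly pick the
    SNP covering (r^2 >= threshold, itself included) the most uncovered
    SNPs, breaking ties toward the earlier position.
    """
    ids = list(ld.index)
    r2 = ld.to_numpy()
    m = len(ids)

    blocks = []
    i = 0
    while i < m:
        j = i
        while j + 1 < m and (r2[i:j + 2, i:j + 2] >= r2_threshold).all():
            j += 1
        if j > i:
            blocks.append(ids[i:j + 1])
            i = j + 1
        else:
            i += 1

    covers = r2 >= r2_threshold
    np.fill_diagonal(covers, True)
    untagged = np.ones(m, dtype=bool)
    tags = []
    while untagged.any():
        gain = (covers & untagged).sum(axis=1)
        best = int(np.argmax(gain))  # argmax takes the first (lowest position) on ties
        tags.append(ids[best])
        untagged &= ~covers[best]
    return blocks, tags


def haplotype_association(
    block: HaplotypeBlock,
    bmi: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    freq_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-haplotype one-vs-rest regression of BMI on expected dosage.

    Only haplotypes at or above ``freq_floor`` are tested; ``bmi`` and
    ``covariates`` align with ``block.individual_ids``. Returns one row
    per qualifying haplotype with beta per haplotype copy.
    """
    rows = []
    for h, (label, freq) in enumerate(zip(block.haplotypes, block.freqs)):
        if freq < freq_floor:
            continue
        res = additive_regression(
            bmi, block.dosage[:, h], covariates,
            snp_id=label, effect_allele=label, other_allele="rest",
        )
        rows.append((label, float(freq), res.n, res.beta, res.se, res.t_stat, res.p))
    if not rows:
        warnings.warn("no haplotype reaches the frequency floor; empty result")
    return pd.DataFrame(rows, columns=["haplotype", "freq", "n", "beta", "se",
                                       "t_stat", "p"])
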