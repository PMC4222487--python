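import numpy as np
import pandas as pd
import pytest

from oracles import min_tag_cover, two_snp_loglik_grid
from panelgwas.haplotypes import (
    em_haplotype_frequencies,
    find_blocks_and_tags,
    haplotype_association,
    ld_matrix,
    ld_r2,
)
from panelgwas.qc import UndefinedStatisticError
from panelgwas.simulate import simulate_haplotype_pool


def _draw_from_pool(pool, n, rng):
    idx = rng.choice(len(pool.freqs), size=(n, 2), p=pool.freqs)
    return (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]).astype(float)


class TestEm:
    def test_single_snp_recovers_allele_freq(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)[:, None]
        block = em_haplotype_frequencies(g)
        est = dict(zip(block.haplotypes, block.freqs))
        assert est["1"] == pytest.approx(g.sum() / 400, abs=1e-9)

    def test_all_homozygous_is_direct_count(self):
        # 10 individuals 11/11, 6 individuals 00/00, 4 individuals 11/00:
        # wait - hom at every SNP means genotype 0 or 2 at each site
        g = np.array([[2, 2]] * 10 + [[0, 0]] * 6 + [[2, 0]] * 4, dtype=float)
        block = em_haplotype_frequencies(g)
        est = dict(zip(block.haplotypes, block.freqs))
        assert est["11"] == pytest.approx(20 / 40)
        assert est["00"] == pytest.approx(12 / 40)
        assert est["10"] == pytest.approx(8 / 40)

    def test_loglik_beats_grid_search(self, rng):
        """EM reaches at least the best likelihood on a fine simplex grid."""
        pool = simulate_haplotype_pool([0.35, 0.45], 0.4)
        g = _draw_from_pool(pool, 30, rng)
        block = em_haplotype_frequencies(g)
        counts = np.zeros((3, 3), dtype=int)
        for g1, g2 in g.astype(int):
            counts[g1, g2] += 1
        grid_best = two_snp_loglik_grid(counts, step=0.01)
        assert block.log_likelihood >= grid_best - 1e-8

    def test_dosage_rows_sum_to_two(self, rng):
        pool = simulate_haplotype_pool([0.3, 0.2, 0.4], 0.3)
        g = _draw_from_pool(pool, 120, rng)
        g[rng.random(g.shape) < 0.05] = np.nan  # missing handled in E-step
        block = em_haplotype_frequencies(g)
        np.testing.assert_allclose(block.dosage.sum(axis=1), 2.0, atol=1e-8)

    def test_freqs_sum_to_one_and_marginals_match(self, rng):
        pool = simulate_haplotype_pool([0.3, 0.4], 0.6)
        g = _draw_from_pool(pool, 400, rng)
        block = em_haplotype_frequencies(g)
        assert block.freqs.sum() == pytest.approx(1.0, abs=1e-8)
        # implied allele-1 frequency at SNP0 equals genotype-based frequency
        implied = sum(f for h, f in zip(block.haplotypes, block.freqs) if h[0] == "1")
        assert implied == pytest.approx(g[:, 0].mean() / 2, abs=1e-6)

    def test_block_size_limit(self):
        with pytest.raises(ValueError, match="8-SNP"):
            em_haplotype_frequencies(np.zeros((4, 9)))

    def test_high_missing_individuals_dropped(self):
        g = np.array([[1, 1, 1, 1], [np.nan, np.nan, np.nan, 0]], dtype=float)
        block = em_haplotype_frequencies(g)
        assert block.n_dropped == 1
        assert len(block.individual_ids) == 1


class TestLdR2:
    def test_self_is_one(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        assert ld_r2(g, g) == pytest.approx(1.0, abs=1e-6)

    def test_perfect_ld_pair(self, rng):
        pool = simulate_haplotype_pool([0.3, 0.3], 1.0)
        g = _draw_from_pool(pool, 300, rng)
        assert ld_r2(g[:, 0], g[:, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_generating_pool_at_large_n(self, rng):
        """Estimated r^2 approaches the analytic pool value D^2/(pq pq)."""
        pool = simulate_haplotype_pool([0.25, 0.4], 0.45)
        g = _draw_from_pool(pool, 20000, rng)
        est = ld_r2(g[:, 0], g[:, 1])
        assert est == pytest.approx(0.45, abs=0.03)

    def test_monomorphic_undefined(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(UndefinedStatisticError):
            ld_r2(g, np.zeros(100))

    def test_symmetric_and_relabel_invariant(self, rng):
        pool = simulate_haplotype_pool([0.3, 0.45], 0.3)
        g = _draw_from_pool(pool, 500, rng)
        a, b = g[:, 0], g[:, 1]
        assert ld_r2(a, b) == pytest.approx(ld_r2(b, a), abs=1e-9)
        assert ld_r2(2 - a, b) == pytest.approx(ld_r2(a, b), abs=1e-9)


class TestBlocksAndTags:
    def test_all_correlated_one_block_one_tag(self):
        ld = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
        blocks, tags = find_blocks_and_tags(ld)
        assert blocks == [list("abcd")]
        assert tags == ["a"]

    def test_all_independent_every_snp_tags_itself(self):
        ld = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        blocks, tags = find_blocks_and_tags(ld)
        assert blocks == []
        assert tags == list("abcd")

    def test_greedy_matches_exhaustive_minimum(self, rng):
        """With a planted 5-SNP block, greedy tagging is minimum-cover optimal."""
        pools = [simulate_haplotype_pool([0.3] * 5, 0.92)]
        names = [f"s{k}" for k in range(8)]
        g = np.column_stack([
            _draw_from_pool(pools[0], 600, rng),
            rng.binomial(2, 0.4, (600, 3)),
        ]).astype(float)
        from panelgwas.types import GenotypeMatrix

        gm = GenotypeMatrix(
            individual_ids=[f"i{k}" for k in range(600)],
            snp_ids=names,
            counts=g,
            count_allele={s: "A" for s in names},
            other_allele={s: "G" for s in names},
        )
        ld = ld_matrix(gm)
        blocks, tags = find_blocks_and_tags(ld, r2_threshold=0.8)
        covers = (ld.to_numpy() >= 0.8)
        np.fill_diagonal(covers, True)
        assert len(tags) == min_tag_cover(covers)
        assert any(set(b) >= {"s0", "s1", "s2", "s3", "s4"} for b in blocks)


class TestHaplotypeAssociation:
    def test_exact_fit_on_phased_data(self, rng):
        """BMI = 1.5 x copies of one haplotype, fully phased: beta exact."""
        pool = simulate_haplotype_pool([0.4, 0.4], 1.0)  # two haplotypes: 11, 00
        idx = rng.choice(len(pool.freqs), size=(120, 2), p=pool.freqs)
        g = (pool.haplotypes[idx[:, 0]] + pool.haplotypes[idx[:, 1]]).astype(float)
        copies_11 = (pool.haplotypes[idx[:, 0]][:, 0] == 1).astype(float) + \
                    (pool.haplotypes[idx[:, 1]][:, 0] == 1).astype(float)
        block = em_haplotype_frequencies(g)
        result = haplotype_association(block, 1.5 * copies_11).set_index("haplotype")
        assert result.loc["11", "beta"] == pytest.approx(1.5, abs=1e-8)
        assert result.loc["00", "beta"] == pytest.approx(-1.5, abs=1e-8)

    def test_rare_haplotype_below_floor_absent(self, rng):
        pool = simulate_haplotype_pool([0.3, 0.3], 0.2)
        g = _draw_from_pool(pool, 500, rng)
        block = em_haplotype_frequencies(g)
        out = haplotype_association(block, rng.normal(27, 4, len(g)), freq_floor=0.3)
        kept = set(out["haplotype"])
        for h, f in zip(block.haplotypes, block.freqs):
            assert (h in kept) == (f >= 0.3)

    def test_permuted_bmi_p_is_uniform(self, rng):
        """Under a permuted outcome the haplotype p-values behave as a null."""
        pool = simulate_haplotype_pool([0.4, 0.35], 0.3)
        g = _draw_from_pool(pool, 150, rng)
        block = em_haplotype_frequencies(g)
        bmi = rng.normal(27, 4, 150)
        ps = []
        for _ in range(120):
            out = haplotype_association(block, rng.permutation(bmi))
            ps.extend(out["p"])
        ps = np.asarray(ps)
        assert 0.40 < ps.mean() < 0.60
        assert 0.01 < (ps < 0.05).mean() < 0.11
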