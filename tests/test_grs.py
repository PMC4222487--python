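import numpy as np
import pandas as pd
import pytest

from oracles import auc_pair_enumeration
from panelgwas.grs import (
    GrsWeights,
    auc_obesity,
    compute_wgrs,
    grouped_score_bins,
    incremental_r2,
    quintile_gradient,
    score_bmi_correlation,
    select_grs_snps,
)
from panelgwas.qc import UndefinedStatisticError
from panelgwas.types import GenotypeMatrix


def _weights(snps, alleles, w):
    return GrsWeights(table=pd.DataFrame(
        {"snp_id": snps, "risk_allele": alleles, "weight": w}))


def _matrix(counts, snps, alleles=None):
    counts = np.asarray(counts, dtype=float)
    alleles = alleles or ["A"] * len(snps)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(counts.shape[0])],
        snp_ids=list(snps),
        counts=counts,
        count_allele=dict(zip(snps, alleles)),
        other_allele={s: ("G" if a != "G" else "C") for s, a in zip(snps, alleles)},
    )


class TestSelection:
    def _table(self, betas_by_analysis):
        rows = []
        for analysis, betas in betas_by_analysis.items():
            for k, b in enumerate(betas):
                rows.append(dict(snp_id=f"rs{k}", cohort=analysis, a1="A", a2="G",
                                 beta=b))
        return pd.DataFrame(rows)

    def test_all_negative_empty(self):
        t = self._table({"c1": [-1, -2], "c2": [-1, -2], "POOLED": [-1, -2]})
        with pytest.warns(UserWarning):
            w = select_grs_snps(t, cohorts=("c1", "c2"))
        assert len(w) == 0

    def test_positive_in_two_of_three_excluded(self):
        t = self._table({"c1": [0.5, 0.4], "c2": [0.5, 0.4], "POOLED": [0.5, -0.1]})
        w = select_grs_snps(t, cohorts=("c1", "c2"))
        assert w.snp_ids == ["rs0"]

    def test_flipped_allele_harmonized_before_sign_test(self):
        # rs0 positive everywhere once c2's effect allele (G, beta -0.3) flips
        rows = [
            dict(snp_id="rs0", cohort="c1", a1="A", a2="G", beta=0.5),
            dict(snp_id="rs0", cohort="c2", a1="G", a2="A", beta=-0.3),
            dict(snp_id="rs0", cohort="POOLED", a1="A", a2="G", beta=0.4),
        ]
        w = select_grs_snps(pd.DataFrame(rows), cohorts=("c1", "c2"))
        assert w.snp_ids == ["rs0"]
        assert w.table.loc[0, "risk_allele"] == "A"
        assert w.table.loc[0, "weight"] == pytest.approx(0.4)


class TestComputeWgrs:
    def test_hand_arithmetic(self):
        """weights (0.30, 0.12, 0.18), genotype (2,1,0): 0.72/0.20 = 3.6 -> 4."""
        gm = _matrix([[2, 1, 0]], ["a", "b", "c"])
        w = _weights(["a", "b", "c"], ["A", "A", "A"], [0.30, 0.12, 0.18])
        out = compute_wgrs(gm, w)
        assert out.loc[0, "raw_score"] == pytest.approx(3.6)
        assert out.loc[0, "integer_score"] == 4

    def test_equal_weights_recover_allele_count(self, rng):
        counts = rng.integers(0, 3, (40, 5)).astype(float)
        gm = _matrix(counts, [f"s{k}" for k in range(5)])
        w = _weights([f"s{k}" for k in range(5)], ["A"] * 5, [0.25] * 5)
        out = compute_wgrs(gm, w)
        np.testing.assert_allclose(out["raw_score"], counts.sum(axis=1))
        np.testing.assert_array_equal(out["integer_score"], counts.sum(axis=1))

    def test_zero_genotype_scores_zero(self):
        gm = _matrix([[0, 0]], ["a", "b"])
        out = compute_wgrs(gm, _weights(["a", "b"], ["A", "A"], [0.3, 0.2]))
        assert out.loc[0, "integer_score"] == 0

    def test_weight_rescaling_invariance(self, rng):
        counts = rng.integers(0, 3, (30, 4)).astype(float)
        gm = _matrix(counts, list("abcd"))
        w1 = _weights(list("abcd"), ["A"] * 4, [0.3, 0.1, 0.2, 0.25])
        w2 = _weights(list("abcd"), ["A"] * 4, [3.0, 1.0, 2.0, 2.5])
        out1 = compute_wgrs(gm, w1)
        out2 = compute_wgrs(gm, w2)
        np.testing.assert_allclose(out1["raw_score"], out2["raw_score"], atol=1e-12)

    def test_missing_imputed_as_twice_frequency(self):
        counts = np.array([[2.0], [1.0], [0.0], [np.nan]])
        gm = _matrix(counts, ["a"])
        out = compute_wgrs(gm, _weights(["a"], ["A"], [0.2]))
        # risk-allele frequency among called: 3/6
        assert out.loc[3, "raw_score"] == pytest.approx(1.0)
        assert len(out) == 4

    def test_missing_drop_mode(self):
        counts = np.array([[2.0], [np.nan]])
        gm = _matrix(counts, ["a"])
        out = compute_wgrs(gm, _weights(["a"], ["A"], [0.2]), missing="drop")
        assert list(out["individual_id"]) == ["i0"]

    def test_risk_allele_orientation(self):
        gm = _matrix([[0, 2]], ["a", "b"], alleles=["A", "A"])
        # risk allele of 'a' is the OTHER allele: count flips 0 -> 2
        w = GrsWeights(table=pd.DataFrame({
            "snp_id": ["a", "b"],
            "risk_allele": [gm.other_allele["a"], "A"],
            "weight": [0.2, 0.2],
        }))
        out = compute_wgrs(gm, w)
        assert out.loc[0, "raw_score"] == pytest.approx(4.0)


class TestQuintiles:
    def test_exact_fit_recovers_scaled_score_means(self, rng):
        score = rng.integers(0, 9, 600)
        bmi = 0.5 * score
        out = quintile_gradient(score, bmi, age=np.full(600, 50.0),
                                sex=np.array(["male"] * 600))
        t = out["table"]
        np.testing.assert_allclose(t["adj_bmi"], 0.5 * t["mean_score"], atol=1e-8)
        assert out["q5_minus_q1"] == pytest.approx(
            0.5 * (t["mean_score"].iloc[-1] - t["mean_score"].iloc[0]), abs=1e-8)

    def test_independent_score_gives_null_gradient(self, rng):
        diffs = []
        for _ in range(60):
            score = rng.integers(0, 9, 400)
            bmi = rng.normal(27, 4, 400)
            out = quintile_gradient(score, bmi, np.full(400, 50.0),
                                    np.array(["male"] * 400))
            diffs.append(out["q5_minus_q1"])
        mc_se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2.5 * mc_se + 0.05

    def test_bmi_shift_invariance(self, rng):
        score = rng.integers(0, 9, 300)
        bmi = rng.normal(27, 4, 300) + 0.2 * score
        age = rng.normal(50, 10, 300)
        sex = rng.choice(["male", "female"], 300)
        out1 = quintile_gradient(score, bmi, age, sex)
        out2 = quintile_gradient(score, bmi + 10.0, age, sex)
        np.testing.assert_allclose(out2["table"]["adj_bmi"],
                                   out1["table"]["adj_bmi"] + 10.0, atol=1e-8)
        assert out2["q5_minus_q1"] == pytest.approx(out1["q5_minus_q1"], abs=1e-8)

    def test_ties_go_to_lower_quintile(self):
        from panelgwas.grs import quintile_assignments
        score = np.array([1, 1, 1, 1, 2, 2, 3, 3, 4, 5])
        q = quintile_assignments(score)
        # all the tied 1s share the lowest quintile
        assert len(set(q[score == 1])) == 1


class TestCorrelationAndAuc:
    def test_perfect_correlation(self):
        s = np.arange(10)
        r, p = score_bmi_correlation(s, s.astype(float))
        assert r == pytest.approx(1.0)

    def test_hand_fixture(self):
        s = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        y = np.array([25.0, 26, 25.5, 27, 26.5, 28, 27.5, 29, 28.5, 30])
        sx = s - s.mean()
        sy = y - y.mean()
        r_hand = (sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum())
        r, _ = score_bmi_correlation(s, y)
        assert r == pytest.approx(r_hand, abs=1e-12)

    def test_constant_score_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            score_bmi_correlation(np.ones(10), np.arange(10.0))

    def test_auc_perfect_separation(self):
        assert auc_obesity([1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_auc_with_ties_matches_enumeration(self):
        score = np.array([3, 5, 5, 2, 7, 5, 3, 8])
        labels = np.array([0, 0, 1, 0, 1, 1, 1, 0], dtype=bool)
        assert auc_obesity(score, labels) == pytest.approx(
            auc_pair_enumeration(score, labels), abs=1e-12)

    def test_auc_complement_symmetry(self, rng):
        score = rng.permutation(np.arange(20)).astype(float)  # tie-free
        labels = rng.random(20) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert auc_obesity(score, labels) + auc_obesity(-score, labels) == \
            pytest.approx(1.0, abs=1e-12)

    def test_auc_single_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            auc_obesity([1, 2, 3], [1, 1, 1])


def test_incremental_r2_null_is_tiny(rng):
    n = 2000
    score = rng.integers(0, 9, n)
    cov = pd.DataFrame({"age": rng.normal(50, 10, n),
                        "sex": rng.choice(["male", "female"], n)})
    bmi = rng.normal(27, 4, n) + 0.05 * cov["age"]
    assert incremental_r2(score, bmi, cov) < 0.005


def test_grouped_score_bins():
    bins = grouped_score_bins(np.array([0, 2, 3, 5, 6, 9]))
    assert list(bins) == ["<=2", "<=2", "3", "5", ">=6", ">=6"]
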