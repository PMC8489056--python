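"""geNorm: relative quantities, M values, stepwise ranking, V(n/n+1)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import refstab as rs
from refstab.stability_genorm import _m_values

from conftest import random_cq_matrix


def brute_force_m(q: pd.DataFrame) -> dict[str, float]:
    """Independent recomputation of geNorm M from the definition."""
    genes = list(q.index)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = np.log2(q.loc[j].to_numpy() / q.loc[k].to_numpy())
            sds.append(float(np.std(ratios, ddof=1)))
        out[j] = float(np.mean(sds))
    return out


def brute_force_stepwise(q: pd.DataFrame) -> list[str]:
    """Naive re-ranking oracle: repeatedly drop the worst gene."""
    remaining = list(q.index)
    excluded = []
    while len(remaining) > 2:
        M = brute_force_m(q.loc[remaining])
        worst = max(remaining, key=lambda g: (M[g], remaining.index(g)))
        remaining.remove(worst)
        excluded.append(worst)
    return remaining + excluded[::-1]


class TestRelativeQuantities:
    def test_default_transform_is_2_pow_minus_dcq(self):
        m = rs.CqMatrix(
            values=pd.DataFrame({"s1": [18.0], "s2": [20.0]}, index=["A"])
        )
        q = rs.to_relative_quantities(m)
        assert q.q.loc["A"].tolist() == pytest.approx([1.0, 0.25])

    def test_explicit_100_percent_equals_default(self):
        m = rs.CqMatrix(
            values=pd.DataFrame({"s1": [18.0], "s2": [20.0]}, index=["A"])
        )
        q0 = rs.to_relative_quantities(m)
        q1 = rs.to_relative_quantities(m, efficiency_percent=100.0)
        pd.testing.assert_frame_equal(q0.q, q1.q)

    def test_custom_efficiency(self):
        """E = 85% gives q = 1.85^-2 = 0.29218 two cycles above the calibrator."""
        m = rs.CqMatrix(
            values=pd.DataFrame({"s1": [18.0], "s2": [20.0]}, index=["A"])
        )
        q = rs.to_relative_quantities(m, efficiency_percent=85.0)
        assert q.q.loc["A", "s2"] == pytest.approx(1.85**-2, rel=1e-12)
        assert q.q.loc["A", "s2"] == pytest.approx(0.29218, abs=1e-5)

    def test_max_per_gene_is_one(self, study_matrix):
        q = rs.to_relative_quantities(study_matrix)
        np.testing.assert_allclose(q.q.max(axis=1).to_numpy(), 1.0)
        assert (q.q.to_numpy() > 0).all()

    def test_nonpositive_efficiency_rejected(self, three_gene_matrix):
        with pytest.raises(ValueError):
            rs.to_relative_quantities(three_gene_matrix, efficiency_percent=-5.0)


class TestMValues:
    def test_parallel_genes_all_zero(self):
        base = np.array([20.0, 21.0, 23.0, 19.5])
        values = pd.DataFrame(
            [base, base + 3.0, base - 1.0],
            index=["A", "B", "C"],
            columns=[f"s{i}" for i in range(4)],
        )
        q = rs.to_relative_quantities(rs.CqMatrix(values=values))
        assert all(r.M == pytest.approx(0.0, abs=1e-12) for r in rs.genorm_m_values(q))

    def test_three_gene_example_matches_pair_sds(self, three_gene_matrix):
        """log2 q ratios differ from −ΔCq by constants, so M = mean pair SD."""
        q = rs.to_relative_quantities(three_gene_matrix)
        res = {r.gene: r.M for r in rs.genorm_m_values(q)}
        assert res["A"] == pytest.approx(0.5)
        assert res["B"] == pytest.approx(0.5)
        assert res["C"] == pytest.approx(1.0)

    def test_loading_shift_invariance_exact(self, study_matrix):
        q0 = rs.to_relative_quantities(study_matrix)
        base = {r.gene: r.M for r in rs.genorm_m_values(q0)}
        shifted = study_matrix.values + np.random.default_rng(7).normal(
            0, 1.5, size=(1, len(study_matrix.samples))
        )
        q1 = rs.to_relative_quantities(rs.CqMatrix(values=shifted))
        for r in rs.genorm_m_values(q1):
            assert r.M == pytest.approx(base[r.gene], abs=1e-10)

    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        m = random_cq_matrix(np.random.default_rng(seed), n_genes=5, n_samples=8)
        q = rs.to_relative_quantities(m)
        expected = brute_force_m(q.q)
        for r in rs.genorm_m_values(q):
            assert r.M == pytest.approx(expected[r.gene], rel=1e-10)

    def test_three_gene_closed_form(self):
        """For G=3, M_j is the mean of gene j's two pair SDs."""
        m = random_cq_matrix(np.random.default_rng(3), n_genes=3, n_samples=10)
        q = rs.to_relative_quantities(m)
        logq = np.log2(q.q.to_numpy())
        sd01 = np.std(logq[0] - logq[1], ddof=1)
        sd02 = np.std(logq[0] - logq[2], ddof=1)
        sd12 = np.std(logq[1] - logq[2], ddof=1)
        M = {r.gene: r.M for r in rs.genorm_m_values(q)}
        assert M["g0"] == pytest.approx((sd01 + sd02) / 2)
        assert M["g1"] == pytest.approx((sd01 + sd12) / 2)
        assert M["g2"] == pytest.approx((sd02 + sd12) / 2)


class TestStepwise:
    def test_noise_gene_excluded_first(self):
        rng = np.random.default_rng(11)
        base = rng.normal(20, 0.5, size=12)
        values = pd.DataFrame(
            {
                "stable1": base + 1.0,
                "stable2": base + 2.0 + rng.normal(0, 0.02, 12),
                "stable3": base - 1.0 + rng.normal(0, 0.02, 12),
                "noisy": rng.uniform(15, 30, 12),
            },
        ).T
        values.columns = [f"s{i}" for i in range(12)]
        q = rs.to_relative_quantities(rs.CqMatrix(values=values))
        res = {r.gene: r for r in rs.genorm_stepwise_ranking(q)}
        assert res["noisy"].rank == 4

    def test_final_pair_share_top_with_equal_m(self, study_matrix):
        q = rs.to_relative_quantities(study_matrix)
        res = sorted(rs.genorm_stepwise_ranking(q), key=lambda r: r.rank)
        assert res[0].M == pytest.approx(res[1].M, rel=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_matches_naive_reranking_oracle(self, seed):
        m = random_cq_matrix(np.random.default_rng(seed), n_genes=5, n_samples=8)
        q = rs.to_relative_quantities(m)
        expected_order = brute_force_stepwise(q.q)
        got = [r.gene for r in sorted(rs.genorm_stepwise_ranking(q), key=lambda r: r.rank)]
        assert got == expected_order

    def test_m_above_ceiling_flags_unstable(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 0.1, size=20)
        values = pd.DataFrame(
            {
                "A": base,
                "B": base + rng.normal(0, 0.05, 20),
                "wild": base + rng.normal(0, 4.0, 20),
            }
        ).T
        values.columns = [f"s{i}" for i in range(20)]
        q = rs.to_relative_quantities(rs.CqMatrix(values=values))
        single = {r.gene: r for r in rs.genorm_m_values(q)}
        assert single["wild"].M > 1.5
        assert not single["wild"].stable
        stepwise = {r.gene: r for r in rs.genorm_stepwise_ranking(q)}
        assert not stepwise["wild"].stable


class TestPairwiseVariation:
    def test_parallel_genes_give_zero_v_and_optimal_two(self):
        base = np.array([20.0, 21.5, 19.0, 22.0])
        values = pd.DataFrame(
            [base, base + 2, base - 1, base + 0.5],
            index=["A", "B", "C", "D"],
            columns=[f"s{i}" for i in range(4)],
        )
        q = rs.to_relative_quantities(rs.CqMatrix(values=values))
        pv = rs.pairwise_variation_curve(q, ["A", "B", "C", "D"])
        assert pv.V == pytest.approx([0.0, 0.0], abs=1e-12)
        assert pv.optimal_n == 2

    def test_impossible_threshold_falls_back_to_all_genes(self, study_matrix):
        q = rs.to_relative_quantities(study_matrix)
        pv = rs.pairwise_variation_curve(q, list(study_matrix.genes), threshold=0.0)
        assert pv.optimal_n == len(study_matrix.genes)

    def test_two_clean_references_pass_threshold_in_majority_of_seeds(self):
        """With exactly 2 near-noiseless genes of 7, V2/3 < 0.15 usually holds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            # default panel with its two most stable genes made near-noiseless
            cfg = rs.default_config(seed=seed)
            for i in range(2):
                g = cfg.genes[i]
                cfg.genes[i] = rs.GeneSpec(g.name, g.mu, 0.014, 0.014)
            ds = rs.generate_cq_dataset(cfg)
            m = rs.collapse_replicates(ds.records, meta=ds.meta)
            q = rs.to_relative_quantities(m)
            order = [
                r.gene
                for r in sorted(rs.genorm_stepwise_ranking(q), key=lambda r: r.rank)
            ]
            pv = rs.pairwise_variation_curve(q, order)
            if pv.V[0] < 0.15:
                hits += 1
        assert hits > n_seeds / 2
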