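import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transomics.rra import (
    RRAConfig,
    aggregate,
    beta_scores,
    normalized_ranks,
    permutation_oracle,
    rho_score,
    truncate_top_fraction,
)
from transomics.validation import null_rho_coverage

ranks_strategy = st.lists(
    st.floats(min_value=1e-6, max_value=1.0, allow_nan=False), min_size=1, max_size=5
)


def _gene_frame(pvals, prefix="g"):
    return pd.DataFrame(
        {"gene_id": [f"{prefix}{i:04d}" for i in range(len(pvals))], "min_p": pvals}
    )


class TestTruncation:
    def test_top_fraction_counts(self):
        assert len(truncate_top_fraction(_gene_frame(np.linspace(0, 1, 100)), 0.05)) == 5
        assert len(truncate_top_fraction(_gene_frame(np.linspace(0, 1, 43)), 0.05)) == 3

    def test_fraction_one_is_identity_in_p_order(self):
        rng = np.random.default_rng(0)
        frame = _gene_frame(rng.random(30))
        out = truncate_top_fraction(frame, 1.0)
        assert len(out) == 30
        assert out["min_p"].is_monotonic_increasing

    def test_ties_break_on_gene_id(self):
        frame = pd.DataFrame({"gene_id": ["b", "a"], "min_p": [0.5, 0.5]})
        out = truncate_top_fraction(frame, 1.0)
        assert list(out["gene_id"]) == ["a", "b"]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            truncate_top_fraction(_gene_frame([]), 0.05)


class TestNormalizedRanks:
    def test_rank_over_universe(self):
        lists = {"genotype": _gene_frame([0.001]).assign(gene_id=["g1"])}
        r = normalized_ranks(lists, {"genotype": 100})
        assert r.loc["g1", "r_genotype"] == pytest.approx(0.01)

    def test_absent_gene_gets_one(self):
        lists = {
            "genotype": pd.DataFrame({"gene_id": ["g1"], "min_p": [0.001]}),
            "expression": pd.DataFrame({"gene_id": ["g2"], "min_p": [0.002]}),
        }
        r = normalized_ranks(lists, {"genotype": 10, "expression": 10})
        assert r.loc["g2", "r_genotype"] == 1.0
        assert r.loc["g1", "r_expression"] == 1.0

    def test_three_gene_example(self):
        lst = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "min_p": [0.001, 0.01, 0.5]}
        )
        r = normalized_ranks({"genotype": lst}, {"genotype": 3})
        np.testing.assert_allclose(
            r["r_genotype"].to_numpy(), [1 / 3, 2 / 3, 1.0]
        )


class TestBetaScores:
    def test_certain_and_single_list(self):
        np.testing.assert_allclose(beta_scores(np.array([1.0, 1.0, 1.0])), [1, 1, 1])
        np.testing.assert_allclose(beta_scores(np.array([0.5])), [0.5])

    def test_closed_form_triplet(self):
        # binomial tail sums for r=(0.1,0.2,0.3):
        # b1 = 1-0.9^3, b2 = 3*0.04*0.8+0.008, b3 = 0.3^3
        beta = beta_scores(np.array([0.1, 0.2, 0.3]))
        np.testing.assert_allclose(beta, [0.271, 0.104, 0.027], atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            beta_scores(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            beta_scores(np.array([1.2]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(ranks_strategy)
    def test_beta_in_unit_interval_and_sorted_input_invariant(self, r):
        r = np.asarray(r)
        beta = beta_scores(r)
        assert ((beta >= 0) & (beta <= 1 + 1e-12)).all()
        np.testing.assert_allclose(beta, beta_scores(np.sort(r)[::-1]), atol=1e-12)

    def test_monte_carlo_oracle_agreement(self):
        """Analytic beta scores match the shuffling oracle within MC error."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            r = rng.uniform(0.01, 1.0, 3)
            analytic = float(np.min(beta_scores(r)))
            mc = permutation_oracle(r, n_draws=200_000, seed=9)
            assert mc == pytest.approx(analytic, abs=0.01)


class TestRhoScore:
    def test_examples(self):
        cfg = RRAConfig(n_lists=3, top_fraction=0.05)
        rho, k = rho_score(np.array([1.0, 1.0, 1.0]), cfg)
        assert rho == 1.0
        rho, k = rho_score(np.array([0.271, 0.104, 0.027]), cfg)
        assert rho == pytest.approx(0.081)
        assert k == 3
        rho, _ = rho_score(np.array([0.5]), RRAConfig(n_lists=1))
        assert rho == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rho_score(np.array([]), RRAConfig())

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(ranks_strategy, st.integers(min_value=0, max_value=4))
    def test_improving_one_rank_never_increases_rho(self, r, idx):
        r = np.asarray(r)
        idx = idx % len(r)
        better = r.copy()
        better[idx] = better[idx] / 2
        cfg = RRAConfig(n_lists=len(r))
        rho_before, _ = rho_score(beta_scores(r), cfg)
        rho_after, _ = rho_score(beta_scores(better), cfg)
        assert rho_after <= rho_before + 1e-12

    def test_single_list_reduces_to_normalized_rank(self):
        cfg = RRAConfig(n_lists=1, correction="bonferroni")
        for r in (0.01, 0.3, 0.99):
            rho, _ = rho_score(beta_scores(np.array([r])), cfg)
            assert rho == pytest.approx(r)


class TestPermutationOracle:
    def test_certain_event(self):
        assert permutation_oracle(np.array([1.0, 1.0, 1.0]), 10**4, seed=1) == 1.0

    def test_seed_determinism(self):
        r = np.array([0.1, 0.4, 0.7])
        a = permutation_oracle(r, 10**4, seed=3)
        b = permutation_oracle(r, 10**4, seed=3)
        assert a == b

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            permutation_oracle(np.array([0.5]), 100, seed=0)


class TestAggregate:
    def _tables(self, pvals_by_omics):
        return {o: _gene_frame(p) for o, p in pvals_by_omics.items()}

    def test_concordant_gene_beats_single_list_gene(self):
        rng = np.random.default_rng(2)
        n = 100
        tables = {}
        for o in ("genotype", "methylation", "expression"):
            p = rng.uniform(0.2, 1.0, n)
            tables[o] = _gene_frame(p)
        # gene 0 strong everywhere; gene 1 strong in one list only
        for o in tables:
            tables[o].loc[0, "min_p"] = 1e-4
        tables["genotype"].loc[1, "min_p"] = 1e-4
        scores = aggregate(tables, RRAConfig(3, 0.05)).set_index("gene_id")
        assert scores.loc["g0000", "trans_omic_score"] < scores.loc["g0001", "trans_omic_score"]

    def test_identical_lists_preserve_p_order(self):
        rng = np.random.default_rng(3)
        p = rng.random(40)
        tables = {o: _gene_frame(p) for o in ("genotype", "methylation", "expression")}
        scores = aggregate(tables, RRAConfig(3, 1.0, correction="none"))
        order_p = _gene_frame(p).sort_values(["min_p", "gene_id"])["gene_id"]
        assert list(scores["gene_id"]) == list(order_p)

    def test_truncation_consistency_inside_all_lists(self):
        """A gene in every truncated list scores identically with and
        without truncation when the universe sizes stay fixed."""
        rng = np.random.default_rng(4)
        p = {o: rng.random(200) for o in ("genotype", "methylation", "expression")}
        for o in p:
            p[o][7] = 1e-6  # gene 7 at the top of every list
        tables = {o: _gene_frame(v) for o, v in p.items()}
        s_trunc = aggregate(tables, RRAConfig(3, 0.05)).set_index("gene_id")
        s_full = aggregate(tables, RRAConfig(3, 1.0)).set_index("gene_id")
        assert s_trunc.loc["g0007", "trans_omic_score"] == pytest.approx(
            s_full.loc["g0007", "trans_omic_score"], rel=1e-12
        )

    def test_per_omics_p_columns_attached(self):
        tables = {
            "genotype": _gene_frame([0.001, 0.5]),
            "methylation": _gene_frame([0.9, 0.002]),
        }
        scores = aggregate(tables, RRAConfig(3, 1.0)).set_index("gene_id")
        assert scores.loc["g0000", "p_genomics"] == 0.001
        assert scores.loc["g0001", "p_epigenomics"] == 0.002

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate({"genotype": _gene_frame([])}, RRAConfig(3, 0.05))

    def test_null_validity_quick(self):
        """Corrected rho is a conservative p-value under independent
        uniform lists (small version of the full calibration study)."""
        cov = null_rho_coverage(n_genes=500, n_reps=60, seed=6)
        for alpha, (mean, se) in cov.items():
            assert mean <= alpha + 3 * se
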