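"""Association-stage tests.

The batched fitters are checked against independent per-feature fits:
statsmodels GLM/OLS with cluster covariance and lifelines CoxPHFitter with a
cluster column.  Properties: null p-value uniformity, affine invariance,
robust-vs-naive ordering under family correlation, and the degenerate-input
contracts.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import kstest

from transomics import _batched
from transomics.association import run_all as assoc_run_all
from transomics import association as assoc
from transomics.simulate import OmicsDataset, SimulationConfig, simulate_cohort


def _merged_design(cohort, omics_type, outcome_cols):
    """Rebuild the analysis frame the association layer uses (sorted by
    family, base covariates + the omics' technical covariate)."""
    cov = cohort["covariates"].set_index("sample_id")
    out = cohort["outcomes"].set_index("sample_id")
    frame = cov.join(out[outcome_cols]).sort_values("family_id", kind="stable")
    cols = ["age", "sex", "weight", "height", f"tech_{omics_type}"]
    return frame, cols


class TestCrossCheckOracles:
    def test_logistic_matches_statsmodels(self, small_cohort):
        ds = small_cohort["omics"]["genotype"]
        table = assoc.test_binary(
            ds, small_cohort["outcomes"].set_index("sample_id")["cac_present"],
            small_cohort["covariates"],
        ).table
        frame, cols = _merged_design(small_cohort, "genotype", ["cac_present"])
        feats = ds.to_frame().loc[frame.index]
        X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in cols])
        for fid in ds.feature_ids[:5]:
            m = sm.GLM(
                frame["cac_present"].to_numpy(float),
                np.column_stack([X, feats[fid]]),
                family=sm.families.Binomial(),
            ).fit(cov_type="cluster", cov_kwds={"groups": frame["family_id"]})
            row = table.set_index("feature_id").loc[fid]
            assert row["estimate"] == pytest.approx(m.params[-1], abs=1e-8)
            assert row["std_error"] == pytest.approx(m.bse[-1], rel=1e-6)

    def test_linear_matches_statsmodels_cr1(self, small_cohort):
        """The CR1 variant reproduces statsmodels OLS cluster SEs exactly;
        the default CR2 estimate is identical with a nearby SE."""
        ds = small_cohort["omics"]["expression"]
        frame, cols = _merged_design(small_cohort, "expression", ["cac_score"])
        frame = frame.dropna(subset=["cac_score"])
        y = np.log(frame["cac_score"].to_numpy(float))
        feats = ds.to_frame().loc[frame.index].to_numpy()
        X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in cols])
        groups = frame["family_id"].to_numpy()
        fit1 = _batched.linear_cluster(X, feats[:, :5], y, groups, small_sample="cr1")
        fit2 = _batched.linear_cluster(X, feats[:, :5], y, groups, small_sample="cr2")
        for j in range(5):
            m = sm.OLS(y, np.column_stack([X, feats[:, j]])).fit(
                cov_type="cluster", cov_kwds={"groups": groups}
            )
            assert fit1.estimate[j] == pytest.approx(m.params[-1], abs=1e-10)
            assert fit1.se_robust[j] == pytest.approx(m.bse[-1], rel=1e-8)
            assert fit2.estimate[j] == pytest.approx(m.params[-1], abs=1e-10)
            assert fit2.se_robust[j] == pytest.approx(m.bse[-1], rel=0.25)

    def test_cox_matches_lifelines(self, small_cohort):
        ds = small_cohort["omics"]["methylation"]
        out = small_cohort["outcomes"].set_index("sample_id")
        incident_time = out["mi_time"].where(out["mi_prevalent"] == 0)
        table = assoc.test_survival(
            ds, incident_time, out["mi_event"], small_cohort["covariates"]
        ).table
        frame, cols = _merged_design(small_cohort, "methylation", ["mi_time", "mi_event", "mi_prevalent"])
        frame = frame.loc[frame["mi_prevalent"] == 0].dropna(subset=["mi_time"])
        feats = ds.to_frame().loc[frame.index]
        checked = 0
        for fid in ds.feature_ids[:4]:
            row = table.set_index("feature_id").loc[fid]
            if row["flag"] != "ok":
                continue
            df = frame[cols + ["mi_time", "mi_event", "family_id"]].copy()
            df["feat"] = feats[fid]
            cph = CoxPHFitter()
            cph.fit(
                df, "mi_time", "mi_event", cluster_col="family_id",
                formula="+".join(cols) + "+feat",
            )
            assert row["estimate"] == pytest.approx(cph.params_["feat"], rel=1e-4, abs=1e-6)
            assert row["std_error"] == pytest.approx(
                cph.standard_errors_["feat"], rel=0.05
            )
            checked += 1
        assert checked >= 2


class TestProperties:
    def test_null_p_values_uniform(self, small_cohort):
        """Under the global null every table's p-values are ~uniform."""
        table = assoc.test_binary(
            small_cohort["omics"]["genotype"],
            small_cohort["outcomes"].set_index("sample_id")["cac_present"],
            small_cohort["covariates"],
        ).table
        stat = kstest(table["p_value"], "uniform").statistic
        assert stat < 0.12  # 120 features

    def test_continuous_null_uniform_at_scale(self):
        cfg = SimulationConfig(
            n_samples=1000,
            n_genes=500,
            features_per_gene_by_omics={"expression": 2},
            seed=21,
        )
        omics, cov, _, out = simulate_cohort(cfg)
        table = assoc.test_continuous(
            omics["expression"], out.set_index("sample_id")["cac_score"], cov
        ).table
        assert kstest(table["p_value"], "uniform").statistic < 0.05

    def test_affine_rescaling_leaves_p_unchanged(self, small_cohort):
        ds = small_cohort["omics"]["expression"]
        scaled = OmicsDataset(
            "expression", ds.sample_ids, ds.feature_ids, ds.values * 137.0 + 5.0
        )
        y = small_cohort["outcomes"].set_index("sample_id")["cac_present"]
        p1 = assoc.test_binary(ds, y, small_cohort["covariates"]).table["p_value"]
        p2 = assoc.test_binary(scaled, y, small_cohort["covariates"]).table["p_value"]
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_singleton_clusters_reduce_to_heteroskedastic_sandwich(self):
        """With families of size 1 the clustered computation equals the
        per-observation sandwich (statsmodels with singleton groups)."""
        rng = np.random.default_rng(3)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        f = rng.normal(size=(n, 3))
        y = rng.normal(size=n)
        groups = np.arange(n)
        fit = _batched.linear_cluster(X, f, y, groups, small_sample="cr1")
        for j in range(3):
            m = sm.OLS(y, np.column_stack([X, f[:, j]])).fit(
                cov_type="cluster", cov_kwds={"groups": groups}
            )
            assert fit.se_robust[j] == pytest.approx(m.bse[-1], rel=1e-8)
            assert fit.p_value[j] == pytest.approx(m.pvalues[-1], rel=5e-3)

    def test_robust_exceeds_naive_under_family_correlation(self):
        """Planting a family random intercept makes the cluster-robust SE
        larger than the model-based SE on average (genotype features share
        the family structure)."""
        cfg = SimulationConfig(
            n_samples=1500,
            n_genes=100,
            features_per_gene_by_omics={"genotype": 2},
            family_intercept_sd=1.0,
            seed=31,
        )
        omics, cov, _, out = simulate_cohort(cfg)
        frame = cov.set_index("sample_id").join(
            out.set_index("sample_id")[["cac_score"]]
        )
        frame = frame.dropna(subset=["cac_score"]).sort_values("family_id")
        feats = omics["genotype"].to_frame().loc[frame.index].to_numpy()
        X = np.column_stack(
            [np.ones(len(frame))]
            + [frame[c] for c in ["age", "sex", "weight", "height"]]
        )
        fit = _batched.linear_cluster(
            X, feats, np.log(frame["cac_score"].to_numpy(float)),
            frame["family_id"].to_numpy(),
        )
        assert np.nanmean(fit.se_robust) > np.nanmean(fit.se_naive)


class TestDegenerateContracts:
    def test_constant_feature_flagged(self, small_cohort):
        ds = small_cohort["omics"]["expression"]
        vals = ds.values.copy()
        vals[:, 0] = 4.2
        const = OmicsDataset("expression", ds.sample_ids, ds.feature_ids, vals)
        y = small_cohort["outcomes"].set_index("sample_id")["cac_present"]
        table = assoc.test_binary(const, y, small_cohort["covariates"]).table
        assert table.iloc[0]["flag"] == "degenerate"
        assert table.iloc[0]["p_value"] == 1.0

    def test_separation_flagged_not_crashed(self, small_cohort):
        ds = small_cohort["omics"]["expression"]
        y = small_cohort["outcomes"].set_index("sample_id")["cac_present"]
        vals = ds.values.copy()
        vals[:, 1] = y.loc[ds.sample_ids].to_numpy(float)  # feature == outcome
        sep = OmicsDataset("expression", ds.sample_ids, ds.feature_ids, vals)
        table = assoc.test_binary(sep, y, small_cohort["covariates"]).table
        assert table.iloc[1]["flag"] == "degenerate"

    def test_single_class_outcome_raises(self, small_cohort):
        y = small_cohort["outcomes"].set_index("sample_id")["cac_present"] * 0
        with pytest.raises(ValueError):
            assoc.test_binary(
                small_cohort["omics"]["genotype"], y, small_cohort["covariates"]
            )

    def test_all_censored_raises(self, small_cohort):
        out = small_cohort["outcomes"].set_index("sample_id")
        with pytest.raises(ValueError):
            assoc.test_survival(
                small_cohort["omics"]["genotype"],
                out["mi_time"],
                out["mi_event"] * 0,
                small_cohort["covariates"],
            )

    def test_too_few_continuous_samples_raises(self, small_cohort):
        out = small_cohort["outcomes"].set_index("sample_id")
        score = out["cac_score"].copy()
        score.iloc[8:] = np.nan
        with pytest.raises(ValueError):
            assoc.test_continuous(
                small_cohort["omics"]["genotype"], score, small_cohort["covariates"]
            )


class TestRunAll:
    def test_twelve_tables_full_coverage(self, small_cohort):
        tables = assoc_run_all(
            small_cohort["omics"],
            small_cohort["outcomes"],
            small_cohort["covariates"],
        )
        assert len(tables) == 12
        for (o, y), t in tables.items():
            assert t.omics_type == o and t.outcome == y
            assert list(t.table["feature_id"]) == small_cohort["omics"][o].feature_ids

    def test_missing_samples_shrink_n_used(self, small_cohort):
        ds = small_cohort["omics"]["methylation"]
        keep = ds.sample_ids[: int(0.8 * len(ds.sample_ids))]
        partial = dict(small_cohort["omics"])
        partial["methylation"] = ds.subset_samples(keep)
        tables = assoc_run_all(
            partial, small_cohort["outcomes"], small_cohort["covariates"]
        )
        n_full = tables[("genotype", "cac_present")].table["n_used"].iloc[0]
        n_part = tables[("methylation", "cac_present")].table["n_used"].iloc[0]
        assert n_part == pytest.approx(0.8 * n_full, rel=0.02)

    def test_deterministic(self, small_cohort):
        t1 = assoc_run_all(
            small_cohort["omics"], small_cohort["outcomes"], small_cohort["covariates"]
        )
        t2 = assoc_run_all(
            small_cohort["omics"], small_cohort["outcomes"], small_cohort["covariates"]
        )
        for key in t1:
            pd.testing.assert_frame_equal(t1[key].table, t2[key].table)
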