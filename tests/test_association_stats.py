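import math

import numpy as np
import pandas as pd
import pytest

import commstate as cs
from commstate.association_stats import (
    AssociationError,
    RatioSeries,
    build_covariate_design,
)


def _meta(n, seed=0, with_covariates=True):
    rng = np.random.default_rng(seed)
    sids = [f"s{i}" for i in range(n)]
    base = dict(
        sample_id=sids,
        subject_id=sids,
        timepoint=rng.choice([1, 2, 3], n),
        is_qc_pool=False,
    )
    if with_covariates:
        base.update(
            sex=rng.choice(["female", "male"], n),
            race_ethnicity=rng.choice(["a", "b", "c"], n),
            bmi=rng.normal(24, 3, n),
        )
    return pd.DataFrame(base)


def _feature_table(values, columns, layer="metabolome", tag="pareto_log"):
    values = np.asarray(values, dtype=float)
    return cs.FeatureTable(
        data=pd.DataFrame(
            values, index=[f"met{i}" for i in range(values.shape[0])], columns=columns
        ),
        layer=layer,
        transform_tag=tag,
    )


class TestLogRatio:
    def _taxa(self, prev, bact):
        return cs.FeatureTable(
            data=pd.DataFrame(
                [prev, bact], index=["Prevotella", "Bacteroides"],
                columns=[f"s{i}" for i in range(len(prev))],
            ),
            layer="taxa",
        )

    def test_hand_value(self):
        rs = cs.log_ratio(self._taxa([10], [100]), "Prevotella", "Bacteroides")
        assert rs.values.iloc[0] == pytest.approx(math.log10(11 / 101))

    def test_equal_counts_zero(self):
        rs = cs.log_ratio(self._taxa([7], [7]), "Prevotella", "Bacteroides")
        assert rs.values.iloc[0] == pytest.approx(0.0)

    def test_double_zero_is_zero(self):
        rs = cs.log_ratio(self._taxa([0], [0]), "Prevotella", "Bacteroides")
        assert rs.values.iloc[0] == pytest.approx(0.0)

    def test_missing_genus_errors(self):
        with pytest.raises(AssociationError, match="Blautia"):
            cs.log_ratio(self._taxa([1], [1]), "Blautia", "Bacteroides")


class TestAdjustedAssociations:
    def test_orthogonal_feature_is_null(self):
        rng = np.random.default_rng(42)
        n, m = 500, 20
        meta = _meta(n, seed=42)
        sids = meta["sample_id"].tolist()
        design = build_covariate_design(meta)
        y = RatioSeries(pd.Series(rng.normal(0, 1, n), index=sids), "P", "B", 1.0)
        feats = _feature_table(rng.normal(0, 1, (m, n)), sids)
        res = cs.adjusted_feature_associations(y, feats, design)
        assert res["rho"].abs().max() < 0.2
        assert res["p_adj"].min() > 0.2
        # Bonferroni definition
        assert np.allclose(res["p_adj"], np.minimum(1.0, res["p"] * m))

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(7)
        n, m = 300, 50
        meta = _meta(n, seed=7)
        sids = meta["sample_id"].tolist()
        design = build_covariate_design(meta)
        yv = rng.normal(0, 1, n)
        F = rng.normal(0, 1, (m, n))
        F[0] = yv + rng.normal(0, 0.2, n)
        y = RatioSeries(pd.Series(yv, index=sids), "P", "B", 1.0)
        res = cs.adjusted_feature_associations(y, _feature_table(F, sids), design)
        assert res.loc["met0", "p_adj"] < 0.05
        assert res.loc["met0", "rho"] > 0.9

    def test_constant_covariates_reduce_to_plain_spearman(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        n = 80
        meta = _meta(n, seed=3, with_covariates=False)
        meta["sex"] = "female"
        meta["race_ethnicity"] = "a"
        meta["bmi"] = 22.0
        meta["timepoint"] = 1
        sids = meta["sample_id"].tolist()
        design = build_covariate_design(meta)
        yv = rng.normal(0, 1, n)
        F = rng.normal(0, 1, (3, n))
        y = RatioSeries(pd.Series(yv, index=sids), "P", "B", 1.0)
        res = cs.adjusted_feature_associations(y, _feature_table(F, sids), design)
        for i in range(3):
            plain = spearmanr(yv, F[i]).statistic
            assert res.loc[f"met{i}", "rho"] == pytest.approx(plain, abs=1e-10)

    def test_rank_deficient_design_names_aliased(self):
        n = 50
        meta = _meta(n, seed=1)
        design = build_covariate_design(meta)
        design["bmi_copy"] = design["bmi"]
        rng = np.random.default_rng(1)
        sids = meta["sample_id"].tolist()
        y = RatioSeries(pd.Series(rng.normal(0, 1, n), index=sids), "P", "B", 1.0)
        feats = _feature_table(rng.normal(0, 1, (2, n)), sids)
        with pytest.raises(AssociationError, match="bmi_copy"):
            cs.adjusted_feature_associations(y, feats, design)


class TestExplainedVariance:
    def test_exact_one_hot_predictor(self):
        rng = np.random.default_rng(0)
        n = 60
        g = rng.choice(3, n)
        y = pd.Series(np.array([1.0, 5.0, -2.0])[g], index=range(n))
        blocks = {
            "group": pd.get_dummies(
                pd.Series(g, index=range(n)).astype("category"),
                drop_first=True,
                dtype=float,
            )
        }
        ev = cs.explained_variance(y, blocks).set_index("predictor")
        assert ev.loc["group", "pct_variance"] == pytest.approx(100.0)
        assert ev.loc["residual", "pct_variance"] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_design_order_invariant(self):
        rng = np.random.default_rng(4)
        n = 400
        a = np.tile([-1.0, 1.0], n // 2)
        b = np.repeat([-1.0, 1.0], n // 2)
        y = pd.Series(2 * a + 3 * b + rng.normal(0, 1, n), index=range(n))
        A = pd.DataFrame(dict(a=a), index=range(n))
        B = pd.DataFrame(dict(b=b), index=range(n))
        ev1 = cs.explained_variance(y, {"a": A, "b": B}).set_index("predictor")
        ev2 = cs.explained_variance(y, {"b": B, "a": A}).set_index("predictor")
        assert ev1.loc["a", "pct_variance"] == pytest.approx(
            ev2.loc["a", "pct_variance"], abs=1e-9
        )

    def test_state_effect_share_matches_design(self):
        # y = state effect (variance 1) + noise (variance 1) -> ~50% share
        rng = np.random.default_rng(8)
        n = 2000
        state = np.tile([0, 1, 2, 3], n // 4)  # balanced: effect variance is 1
        effect = np.array([-1.3416, -0.4472, 0.4472, 1.3416])
        y = pd.Series(effect[state] + rng.normal(0, 1, n), index=range(n))
        blocks = {
            "state": pd.get_dummies(
                pd.Series(state, index=range(n)).astype("category"),
                drop_first=True,
                dtype=float,
            )
        }
        ev = cs.explained_variance(y, blocks).set_index("predictor")
        assert ev.loc["state", "pct_variance"] == pytest.approx(50.0, abs=3.0)

    def test_shares_sum_to_hundred(self):
        rng = np.random.default_rng(9)
        n = 100
        y = pd.Series(rng.normal(0, 1, n), index=range(n))
        blocks = {
            "x1": pd.DataFrame(rng.normal(0, 1, (n, 2)), index=range(n)),
            "x2": pd.DataFrame(rng.normal(0, 1, (n, 1)), index=range(n)),
        }
        ev = cs.explained_variance(y, blocks)
        assert ev["pct_variance"].sum() == pytest.approx(100.0, abs=1e-9)
        assert (ev["pct_variance"] >= -1e-12).all()


class TestDissimilarityRegressions:
    def test_exact_linear_outcome(self):
        x = pd.Series(np.arange(10, dtype=float), index=[f"u{i}" for i in range(10)])
        y = 2.0 * x
        res = cs.dissimilarity_regressions(y, x.to_frame("pred"))
        assert res.loc["pred", "beta"] == pytest.approx(2.0)
        assert res.loc["pred", "p"] < 1e-10

    def test_null_predictor_not_significant(self):
        rng = np.random.default_rng(10)
        n = 500
        idx = [f"u{i}" for i in range(n)]
        y = pd.Series(rng.normal(0, 1, n), index=idx)
        preds = pd.DataFrame(dict(noise=rng.normal(0, 1, n)), index=idx)
        res = cs.dissimilarity_regressions(y, preds)
        assert abs(res.loc["noise", "beta"]) < 0.2

    def test_stabilizing_genus_has_negative_beta(self):
        # generator option: subjects rich in the stabiliser genus blend their
        # later compositions toward baseline, lowering intra dissimilarity
        cohort = cs.generate_cohort(
            cs.CohortConfig(n_subjects=60, stabilizer=True, seed=23)
        )
        rel = cs.relative_abundance(cohort.taxa)
        dm = cs.distance_matrix(rel, "bray_curtis")
        part = cs.partition_dissimilarity(dm, cohort.metadata)
        clr = cs.clr_transform(cohort.taxa)
        subj = cohort.metadata.set_index("sample_id")["subject_id"]
        faecali = clr.data.loc["Faecalibacterium"]
        mean_clr = faecali.groupby(subj.loc[faecali.index].to_numpy()).mean()
        res = cs.dissimilarity_regressions(
            part.per_subject_sqrt_median, mean_clr.to_frame("Faecalibacterium")
        )
        assert res.loc["Faecalibacterium", "beta"] < 0
        assert res.loc["Faecalibacterium", "p"] < 0.05

    def test_too_few_subjects_errors(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        with pytest.raises(AssociationError):
            cs.dissimilarity_regressions(x, x.to_frame("p"))


class TestRankTests:
    def test_identical_groups_p_one(self):
        u, p = cs.rank_tests({"a": np.ones(5), "b": np.ones(5)}, "mann_whitney")
        assert p == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        u, p = cs.rank_tests(
            {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6])}, "mann_whitney"
        )
        assert min(u, 9 - u) == pytest.approx(0.0)

    def test_kruskal_hand_value(self):
        h, p = cs.rank_tests(
            {
                "a": np.array([1.0, 2, 3]),
                "b": np.array([4.0, 5, 6]),
                "c": np.array([7.0, 8, 9]),
            },
            "kruskal_wallis",
        )
        assert h == pytest.approx(7.2)

    def test_dunn_pairs_and_bonferroni(self):
        out = cs.rank_tests(
            {
                "a": np.array([1.0, 2, 3]),
                "b": np.array([4.0, 5, 6]),
                "c": np.array([7.0, 8, 9]),
            },
            "dunn",
        )
        assert len(out) == 3
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()

    def test_empty_group_errors(self):
        with pytest.raises(AssociationError):
            cs.rank_tests({"a": np.array([]), "b": np.array([1.0])}, "mann_whitney")
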