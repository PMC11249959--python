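"""Cross-sectional statistics: stratification, FDR, EMMs, associations,
descriptives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from dtialps import (MUTATION_STAGE_FAMILY, STAGE_FAMILY, add_stage4,
                     adjusted_group_comparison, association_model,
                     describe_cohort, expected_onset, fdr_adjust,
                     stratify_alps)


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg: sort, scale by n/rank, running min."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


class TestExpectedOnset:
    @pytest.mark.parametrize("age,onset,expected", [
        (45, 60, -15), (60, 60, 0), (70, 58, 12)])
    def test_examples(self, age, onset, expected):
        assert expected_onset(age, onset) == expected

    def test_missing_family_onset_propagates_nan(self):
        assert np.isnan(expected_onset(50, np.nan))


class TestStratify:
    def test_classes_and_boundaries(self):
        # z = 2 -> high, z = 0 -> average, z = exactly +/-1 -> average
        # (strict inequalities define the extreme classes)
        vals = [2.0, 0.0, 1.0, -1.0, -1.5]
        out = stratify_alps(vals, 0.0, 1.0)
        assert list(out) == ["high", "average", "average", "average", "low"]

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            stratify_alps([1.3], 1.3, 0.0)


class TestFDR:
    @pytest.mark.parametrize("p,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.02, 0.02, 0.02], [0.02, 0.02, 0.02]),
    ])
    def test_known_values(self, p, expected):
        assert np.allclose(fdr_adjust(p), expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_never_decreases_and_capped(self, p):
        adj = fdr_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
           st.integers(0, 10_000))
    def test_permutation_equivariant(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        assert np.allclose(fdr_adjust(np.asarray(p)[perm]),
                           fdr_adjust(p)[perm])

    def test_flat_adjusted_vectors_are_fixed_points(self):
        # a tied step-up result re-adjusts to itself; general monotone
        # vectors need not (the step-up map is not idempotent)
        adj = fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(fdr_adjust(adj), adj)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_readjustment_never_decreases(self, p):
        adj = fdr_adjust(p)
        assert np.all(fdr_adjust(adj) >= adj - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


def _toy_cohort(rng, n_per=30, group_means=(0.0, 0.0), covariate_effect=0.0,
                age_shift=(0.0, 0.0)):
    rows = []
    for gi, mu in enumerate(group_means):
        for _ in range(n_per):
            age = rng.uniform(30, 70) + age_shift[gi]
            rows.append({
                "group": f"g{gi}", "age": age,
                "sex": rng.choice(["F", "M"]),
                "site": rng.choice(["s1", "s2", "s3"]),
                "y": mu + covariate_effect * age + rng.normal(0, 1.0),
            })
    return pd.DataFrame(rows)


class TestGroupComparison:
    def test_no_covariate_effect_balanced_emms_equal_raw_means(self):
        rng = np.random.default_rng(0)
        df = _toy_cohort(rng, n_per=40, group_means=(0.0, 1.0))
        res = adjusted_group_comparison(df, "y", "group", covariates=())
        for g in ("g0", "g1"):
            assert res.emms[g]["emm"] == pytest.approx(
                df.loc[df["group"] == g, "y"].mean(), abs=1e-10)

    def test_emm_recovers_group_shift_despite_confounded_covariate(self):
        """g1 is 10 years older and age drives y; EMMs adjust the bias away."""
        rng = np.random.default_rng(1)
        df = _toy_cohort(rng, n_per=200, group_means=(0.0, 0.5),
                         covariate_effect=0.1, age_shift=(0.0, 10.0))
        res = adjusted_group_comparison(df, "y", "group", covariates=("age",))
        diff = res.emms["g1"]["emm"] - res.emms["g0"]["emm"]
        assert diff == pytest.approx(0.5, abs=0.25)
        raw_diff = (df.loc[df["group"] == "g1", "y"].mean()
                    - df.loc[df["group"] == "g0", "y"].mean())
        assert raw_diff > 1.0  # the unadjusted difference is badly confounded

    def test_contrast_family_is_exactly_what_was_declared(self, default_cohort):
        staged = add_stage4(default_cohort)
        res = adjusted_group_comparison(staged, "alps_mean", "stage4",
                                        family=STAGE_FAMILY)
        assert [(c["a"], c["b"]) for c in res.contrasts] == list(STAGE_FAMILY)
        res9 = adjusted_group_comparison(staged, "alps_mean", "group",
                                         family=MUTATION_STAGE_FAMILY)
        assert len(res9.contrasts) == 9
        for c in res.contrasts + res9.contrasts:
            assert c["p_fdr"] >= c["p_raw"] - 1e-15
            assert c["p_fdr"] <= 1.0

    def test_symptomatic_below_old_nc_detected(self):
        """Power check at the published group sizes and dispersions.

        The implied subject-level SDs leave this contrast with moderate
        power, so significance is asserted as a rate over replicate
        cohorts (far above the 2.5% one-sided chance level), and the
        direction through the mean estimate.
        """
        from dtialps import CohortSpec, make_cohort
        estimates, hits = [], 0
        for seed in range(20):
            staged = add_stage4(make_cohort(CohortSpec(seed=seed)))
            res = adjusted_group_comparison(staged, "alps_mean", "stage4",
                                            family=STAGE_FAMILY)
            c = {(x["a"], x["b"]): x for x in res.contrasts}[
                ("NC_old", "symptomatic")]
            estimates.append(c["estimate"])
            hits += c["p_fdr"] < 0.05
        assert np.mean(estimates) > 0.04  # NC_old clearly above symptomatic
        assert hits >= 5                  # detection far above chance

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(3)
        df = _toy_cohort(rng)
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="collinear.*age2"):
            adjusted_group_comparison(df, "y", "group", covariates=("age", "age2"))

    def test_too_small_groups_rejected(self):
        df = pd.DataFrame({"group": ["a", "b"], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match=">= 2 subjects"):
            adjusted_group_comparison(df, "y", "group", covariates=())


class TestAssociation:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.uniform(0, 1, 50)})
        df["y"] = 2.0 * df["x"]
        fit = association_model(df, "y", "x", covariates=())
        assert fit.beta == pytest.approx(2.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_beta_invariant_to_covariate_shift(self, default_cohort):
        carriers = default_cohort[default_cohort["mutation"] != "NC"].copy()
        f1 = association_model(carriers, "cdr_ftld_latent", "alps_mean")
        carriers["age"] = carriers["age"] + 100.0
        f2 = association_model(carriers, "cdr_ftld_latent", "alps_mean")
        assert f2.beta == pytest.approx(f1.beta, rel=1e-9)

    def test_log_transform_rejects_nonpositive_with_ids(self):
        df = pd.DataFrame({"id": ["a", "b", "c"], "x": [1.0, 2.0, 3.0],
                           "y": [5.0, -1.0, 2.0]})
        with pytest.raises(ValueError, match="b"):
            association_model(df, "y", "x", covariates=(), log_transform_y=True)

    def test_plasma_slope_recovery(self, default_cohort):
        carriers = default_cohort[default_cohort["mutation"] != "NC"]
        fit = association_model(carriers, "nfl", "alps_mean",
                                covariates=("age", "sex", "site", "plasma_site"),
                                log_transform_y=True)
        assert fit.beta == pytest.approx(-0.28, abs=3 * fit.se)


class TestDescribe:
    def test_identical_constants_zero_statistic(self):
        df = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4, "v": [2.0] * 8})
        out = describe_cohort(df, "g")
        assert out.loc[out["variable"] == "v", "p"].iloc[0] == 1.0

    def test_kruskal_matches_rank_sum_oracle(self):
        # 3 groups x 4 values, no ties: H = 12/(N(N+1)) * sum(R_g^2/n_g) - 3(N+1)
        groups = {"a": [1.0, 5.0, 8.0, 11.0], "b": [2.0, 4.0, 9.0, 12.0],
                  "c": [3.0, 6.0, 7.0, 10.0]}
        df = pd.DataFrame([(g, v) for g, vs in groups.items() for v in vs],
                          columns=["g", "v"])
        ranks = sps.rankdata(df["v"])
        n = len(df)
        h = 12 / (n * (n + 1)) * sum(
            ranks[df["g"] == g].sum() ** 2 / 4 for g in groups) - 3 * (n + 1)
        expected_p = sps.chi2.sf(h, 2)
        out = describe_cohort(df, "g")
        assert out["p"].iloc[0] == pytest.approx(expected_p, rel=1e-10)

    def test_proportions_match_textbook_chi_square(self):
        # female counts 29/50 vs 20/33 (the two NC groups)
        df = pd.DataFrame({
            "g": ["young"] * 50 + ["old"] * 33,
            "sex": ["F"] * 29 + ["M"] * 21 + ["F"] * 20 + ["M"] * 13,
        })
        obs = np.array([[29, 21], [20, 13]])
        expct = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        chi2 = ((obs - expct) ** 2 / expct).sum()
        out = describe_cohort(df, "g")
        assert out.loc[out["variable"] == "sex", "p"].iloc[0] == pytest.approx(
            sps.chi2.sf(chi2, 1), rel=1e-10)

    def test_all_missing_variable_omitted_with_warning(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"], "v": [1.0, 2.0, 3.0, 4.0],
                           "w": [np.nan] * 4})
        with pytest.warns(UserWarning, match="all-missing"):
            out = describe_cohort(df, "g")
        assert "w" not in out["variable"].tolist()
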