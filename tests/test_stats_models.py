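"""GLM layer: demographics, family selection, diagnostics, scans."""

import numpy as np
import pandas as pd
import pytest

from dynstates.stats_models import (
    ModelSpec,
    bonferroni_threshold,
    correct_p,
    demographics_tests,
    fit_glm,
    interaction_scan,
    select_family_and_transform,
    vif,
)


def _covariate_frame(n, rng):
    return pd.DataFrame(
        {
            "age": rng.integers(18, 70, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
            "education": rng.integers(1, 8, n).astype(float),
        }
    )


def _interaction_data(n, rng, beta_int=-3.0, noise=1.0):
    data = _covariate_frame(n, rng)
    data["ei"] = rng.normal(size=n)
    data["metric"] = rng.normal(size=n)
    data["y"] = (
        5.0
        + 2.0 * data["ei"]
        - 1.5 * data["metric"]
        + beta_int * data["ei"] * data["metric"]
        + 0.05 * data["age"]
        + noise * rng.normal(size=n)
    )
    return data


SPEC = ModelSpec(response="y", predictors=["ei * metric"])


class TestBonferroni:
    def test_state_family_thresholds(self):
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
        assert bonferroni_threshold(0.05, 25) == pytest.approx(0.002)

    def test_corrected_p_capped(self):
        assert correct_p(0.9, 25) == 1.0
        assert correct_p(0.004, 5) == pytest.approx(0.02)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 5)
        with pytest.raises(ValueError):
            correct_p(0.5, 0)


class TestDemographics:
    def test_perfect_association_chi_square_is_twenty(self):
        cohort = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10,
                "sex": [0] * 10 + [1] * 10,
            }
        )
        out = demographics_tests(cohort, categorical=["sex"])
        row = out.set_index("variable").loc["sex"]
        assert row["statistic"] == pytest.approx(20.0)

    def test_identical_groups_never_reject(self, rng):
        values = rng.normal(size=30)
        cohort = pd.DataFrame(
            {
                "group": ["a"] * 30 + ["b"] * 30,
                "score": np.concatenate([values, values]),
                "cat": [0, 1] * 30,
            }
        )
        out = demographics_tests(cohort, continuous=["score"], categorical=["cat"])
        assert not out["significant"].any()
        assert (out["p"] > 0.9).all()

    def test_planted_shift_detected_with_high_power(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cohort = pd.DataFrame(
                {
                    "group": ["a"] * 50 + ["b"] * 50,
                    "score": np.concatenate(
                        [rng.normal(0, 1, 50), rng.normal(2.0, 1, 50)]
                    ),
                }
            )
            out = demographics_tests(cohort, continuous=["score"])
            hits += out["p"].iloc[0] < 0.001
        assert hits >= 48  # >= 95% of seeds

    def test_alpha_override_for_multi_scale_questionnaires(self, rng):
        cohort = pd.DataFrame(
            {"group": ["a"] * 20 + ["b"] * 20, "neuroticism": rng.normal(size=40)}
        )
        out = demographics_tests(
            cohort,
            continuous=["neuroticism"],
            alpha_overrides={"neuroticism": 0.01},
        )
        assert out["alpha"].iloc[0] == 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            demographics_tests(pd.DataFrame({"group": ["a", "a"]}))


class TestVif:
    def test_closed_form_for_correlated_pair(self, rng):
        x1 = rng.normal(size=500)
        resid = rng.normal(size=500)
        resid -= np.polyval(np.polyfit(x1, resid, 1), x1)  # orthogonalise
        x2 = 0.8 * (x1 - x1.mean()) / x1.std() + np.sqrt(1 - 0.64) * resid / resid.std()
        design = pd.DataFrame({"x1": x1, "x2": x2})
        r2 = np.corrcoef(x1, x2)[0, 1] ** 2
        expected = 1.0 / (1.0 - r2)
        assert vif(design)["x2"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_duplicated_predictor_is_infinite(self, rng):
        x = rng.normal(size=50)
        design = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        v = vif(design)
        assert np.isinf(v["a"]) and np.isinf(v["b"])

    def test_independent_predictors_near_one(self, rng):
        design = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        v = vif(design)
        assert (v >= 1.0).all() and (v <= 1.05).all()

    def test_orthogonal_predictors_exactly_one(self):
        design = pd.DataFrame(
            {"a": [1.0, 1.0, -1.0, -1.0], "b": [1.0, -1.0, 1.0, -1.0]}
        )
        assert np.allclose(vif(design).to_numpy(), 1.0)


class TestFamilySelection:
    def test_dichotomous_forces_binomial(self, rng):
        data = _covariate_frame(40, rng)
        data["ei"] = rng.normal(size=40)
        data["metric"] = rng.normal(size=40)
        data["y"] = rng.integers(0, 2, 40).astype(float)
        family, transform, table = select_family_and_transform(data, SPEC)
        assert family == "binomial"
        assert len(table) == 1

    def test_poisson_counts_select_poisson(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            data = _covariate_frame(200, rng)
            data["ei"] = rng.normal(size=200)
            data["metric"] = rng.normal(size=200)
            mu = np.exp(1.0 + 0.4 * data["ei"] - 0.3 * data["metric"])
            data["y"] = rng.poisson(mu).astype(float)
            family, _, _ = select_family_and_transform(data, SPEC)
            hits += family == "poisson"
        assert hits >= 40

    def test_gaussian_response_selects_gaussian_identity(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            data = _interaction_data(200, rng)
            family, transform, _ = select_family_and_transform(data, SPEC)
            hits += (family, transform) == ("gaussian", "identity")
        assert hits >= 40

    def test_too_few_observations_rejected(self, rng):
        data = _interaction_data(8, rng)
        with pytest.raises(ValueError, match="10"):
            select_family_and_transform(data, SPEC)


class TestFitGlm:
    def test_interaction_recovery_and_orthogonal_vifs(self, rng):
        data = _interaction_data(500, rng)
        res = fit_glm(SPEC, data, family="gaussian")
        coef = res.coefficients.set_index("term")
        est = coef.loc["ei:metric", "estimate"]
        se = coef.loc["ei:metric", "se"]
        assert est == pytest.approx(-3.0, abs=4 * se)
        assert res.accepted
        assert (res.vif < 1.5).all()
        assert res.overall_df == (6, 493)

    def test_rank_deficient_design_names_aliased_terms(self, rng):
        data = _interaction_data(60, rng)
        data["metric"] = data["ei"]  # aliased with ei
        spec = ModelSpec(response="y", predictors=["ei", "metric"])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm(spec, data, family="gaussian")

    def test_corrected_p_respects_family_size(self, rng):
        data = _interaction_data(100, rng)
        spec = ModelSpec(response="y", predictors=["ei * metric"], bonferroni_m=5)
        res = fit_glm(spec, data, family="gaussian")
        assert res.overall_p_corrected == pytest.approx(
            min(1.0, res.overall_p * 5)
        )
        assert res.overall_p_corrected >= res.overall_p

    def test_aic_of_selected_family_is_minimal(self, rng):
        data = _interaction_data(150, rng)
        data["y"] = np.abs(data["y"]) + 1.0  # positive: all families admissible
        family, transform, table = select_family_and_transform(data, SPEC)
        chosen = table.set_index(["family", "transform"]).loc[(family, transform), "aic"]
        assert chosen <= table["aic"].min() + 1e-9


class TestInteractionScan:
    @staticmethod
    def _cohort_and_metrics(seed, beta_int=-4.0):
        from dynstates.state_metrics import StateSequence, cohort_state_summary
        from dynstates.synthetic_cohort import (
            OutcomeBetas,
            default_markov_matrix,
            simulate_markov_sequence,
            simulate_outcomes,
        )

        rng = np.random.default_rng(seed)
        n = 27
        sids = [f"s{i:02d}" for i in range(n)]
        seqs = [
            StateSequence(
                sid, simulate_markov_sequence(
                    default_markov_matrix(5, p_stay=0.9), 200, seed=rng
                ), 1.6,
            )
            for sid in sids
        ]
        _, metrics, _ = cohort_state_summary(seqs, k=5)
        visits3 = (
            metrics[metrics["state"] == 3].set_index("subject_id")["n_visits"]
        )
        cov = pd.DataFrame(
            {
                "age": rng.integers(18, 70, n).astype(float),
                "sex": rng.integers(0, 2, n).astype(float),
                "education": rng.integers(1, 8, n).astype(float),
            },
            index=sids,
        )
        ei = rng.normal(size=n)
        betas = OutcomeBetas(interaction=beta_int, noise_sd=1.5)
        severity, _ = simulate_outcomes(
            ei, visits3.loc[sids].to_numpy(), cov, betas=betas, seed=rng
        )
        cohort = cov.reset_index(names="subject_id")
        cohort["severity_6mo"] = severity.astype(float)
        cohort["emotional_instability"] = ei
        return cohort, metrics

    def test_planted_state3_interaction_found(self):
        hits = 0
        for seed in range(50):
            cohort, metrics = self._cohort_and_metrics(seed)
            out = interaction_scan(cohort, metrics, k=5)
            ok = out[out["overall_p_corrected"].notna()]
            best = ok.loc[ok["overall_p_corrected"].idxmin()]
            hits += (
                best["metric_class"] == "n_visits"
                and best["metric"] == "state3"
                and best["interaction_estimate"] < 0
            )
        assert hits >= 40  # >= 80% of seeds

    def test_family_sizes_by_metric_class(self):
        cohort, metrics = self._cohort_and_metrics(0)
        from dynstates.state_metrics import StateSequence, transition_probabilities
        from dynstates.synthetic_cohort import default_markov_matrix, simulate_markov_sequence

        rng = np.random.default_rng(1)
        trans = pd.concat(
            [
                transition_probabilities(
                    StateSequence(
                        sid,
                        simulate_markov_sequence(
                            default_markov_matrix(5, p_stay=0.9), 200, seed=rng
                        ),
                    ),
                    k=5,
                ).to_frame()
                for sid in cohort["subject_id"]
            ],
            ignore_index=True,
        )
        out = interaction_scan(cohort, metrics, k=5, transitions=trans)
        sizes = out.groupby("metric_class")["bonferroni_m"].unique()
        assert sizes["mean_dwell_seconds"].tolist() == [5]
        assert sizes["n_visits"].tolist() == [5]
        assert sizes["transition_probability"].tolist() == [25]
        assert sizes["n_transitions"].tolist() == [1]

    def test_null_cohort_familywise_error_controlled(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort, metrics = self._cohort_and_metrics(seed + 10_000, beta_int=0.0)
            rng = np.random.default_rng(seed)
            cohort["severity_6mo"] = rng.normal(size=len(cohort))  # pure noise
            out = interaction_scan(cohort, metrics, k=5)
            fam = out[out["metric_class"] == "n_visits"]
            rejections += bool((fam["overall_p_corrected"] < 0.05).any())
        fwer = rejections / n_seeds
        assert fwer <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_seeds)

    def test_unmatched_subjects_listed(self):
        cohort, metrics = self._cohort_and_metrics(2)
        cohort = cohort[cohort["subject_id"] != "s00"]
        with pytest.raises(ValueError, match="s00"):
            interaction_scan(cohort, metrics, k=5)
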