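"""Synthetic cohort generator: prevalence calibration, parameter recovery,
typing-resolution masking, onset model, missingness."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

from rapredict import (
    ModelConfig,
    RiskFactorModel,
    SynthConfig,
    build_categoriser,
    contingency_or,
    generate_cohort,
    generate_onset_ages,
    inject_missingness,
    mask_resolution,
    roc_auc,
    score_cohort,
    simulate_population,
    solve_intercept,
)

from conftest import make_snp


def _config(ids, name="t", prevalence=0.01, sex_restriction="none"):
    return ModelConfig(
        name=name,
        factor_ids=tuple(ids),
        prevalence=prevalence,
        sex_restriction=sex_restriction,
    )


class TestSolveIntercept:
    def test_no_risk_factors_closed_form(self):
        model = RiskFactorModel([make_snp("s0", 1.5, 0.0, 0.1)])
        alpha, shift = solve_intercept(model, _config(["s0"], prevalence=0.01))
        assert shift == pytest.approx(0.0, abs=1e-12)
        assert alpha == pytest.approx(logit(0.01), abs=1e-6)
        assert alpha == pytest.approx(-4.595, abs=1e-3)

    def test_prevalence_half_null_model(self):
        model = RiskFactorModel([make_snp("s0", 1.5, 0.0, 0.1)])
        alpha, _ = solve_intercept(model, _config(["s0"], prevalence=0.5))
        assert alpha == pytest.approx(0.0, abs=1e-9)

    def test_self_consistent_realised_prevalence(self, rng):
        """Simulating disease at the solved intercept reproduces the target."""
        model = RiskFactorModel([make_snp("s1", 2.0, 0.3, 0.05)])
        cfg = _config(["s1"], prevalence=0.05)
        alpha, shift = solve_intercept(model, cfg, n_sim=100_000)
        from rapredict.population import ProfileSampler
        from scipy.special import expit

        sampler = ProfileSampler(cfg, model)
        draws = sampler.sample(1_000_000, rng)
        raw, _ = sampler.log_odds(draws)
        p = expit(alpha + raw - shift)
        realised = float(np.mean(rng.random(p.size) < p))
        se = math.sqrt(0.05 * 0.95 / p.size)
        assert realised == pytest.approx(0.05, abs=3 * se + 5e-4)


class TestGenerateCohort:
    def test_null_model_equal_allele_frequencies(self):
        """All ORs 1: case and control dosage means agree within MC error."""
        model = RiskFactorModel(
            [make_snp("n1", 1.0, 0.3, 0.05), make_snp("n2", 1.0, 0.45, 0.05)]
        )
        cfg = _config(["n1", "n2"])
        synth = SynthConfig(n_cases=3000, n_controls=3000)
        cohort = generate_cohort(model, cfg, synth, seed=5)
        for sid, p in (("n1", 0.3), ("n2", 0.45)):
            ca = cohort.loc[cohort.status == "case", sid].mean()
            co = cohort.loc[cohort.status == "control", sid].mean()
            se = math.sqrt(2 * p * (1 - p) / 3000)
            assert ca == pytest.approx(co, abs=4 * se)

    def test_risk_allele_enriched_in_cases_iff_or_above_one(self):
        model = RiskFactorModel(
            [make_snp("up", 3.0, 0.3, 0.05), make_snp("down", 0.5, 0.3, 0.05)]
        )
        cfg = _config(["up", "down"])
        synth = SynthConfig(n_cases=2000, n_controls=2000)
        cohort = generate_cohort(model, cfg, synth, seed=8)
        ca = cohort[cohort.status == "case"]
        co = cohort[cohort.status == "control"]
        assert ca["up"].mean() > co["up"].mean()
        assert ca["down"].mean() < co["down"].mean()

    def test_smoking_or_recovered_in_males(self, model, configs):
        """Generating under the male ever-smoking OR 3.02 recovers it from
        the output 2x2 table within 15%."""
        synth = SynthConfig(
            n_cases=5000,
            n_controls=5000,
            female_frac_cases=0.0,
            female_frac_controls=0.0,
            prevalence=configs["HLA_smoking"].prevalence,
        )
        cohort = generate_cohort(model, configs["HLA_smoking"], synth, seed=13)
        males = cohort[cohort.sex == "male"]
        a = int(((males.status == "case") & (males.ever_smoker == 1)).sum())
        b = int(((males.status == "case") & (males.ever_smoker == 0)).sum())
        c = int(((males.status == "control") & (males.ever_smoker == 1)).sum())
        d = int(((males.status == "control") & (males.ever_smoker == 0)).sum())
        got = contingency_or(a, b, c, d).odds_ratio
        assert got == pytest.approx(3.02, rel=0.15)

    def test_seeded_determinism(self, toy_model, toy_config):
        synth = SynthConfig(n_cases=300, n_controls=300)
        a = generate_cohort(toy_model, toy_config, synth, seed=21)
        b = generate_cohort(toy_model, toy_config, synth, seed=21)
        pd.testing.assert_frame_equal(a, b)

    def test_design_margins_and_labels(self, toy_model, toy_config):
        synth = SynthConfig(n_cases=400, n_controls=600)
        cohort = generate_cohort(toy_model, toy_config, synth, seed=3)
        assert (cohort.status == "case").sum() == 400
        assert (cohort.status == "control").sum() == 600
        cases = cohort[cohort.status == "case"]
        assert (cases.sex == "female").mean() == pytest.approx(0.76, abs=0.01)
        assert set(cases.serostatus) <= {"acpa_pos", "seropos"}
        assert cohort.loc[cohort.status == "control", "serostatus"].isna().all()


class TestMaskResolution:
    def _cohort(self, model, configs, n=400):
        synth = SynthConfig(n_cases=n // 2, n_controls=n // 2)
        return synth, generate_cohort(model, configs["HLA"], synth, seed=30)

    def test_all_four_digit_unchanged(self, model, configs, rng):
        synth, cohort = self._cohort(model, configs)
        synth = SynthConfig(resolution_mix=(1.0, 0.0, 0.0))
        out = mask_resolution(cohort, synth, rng)
        assert (out.hla_1 == out.hla_true_1).all()
        assert (out.hla_2 == out.hla_true_2).all()

    def test_all_two_digit_collapsed(self, model, configs, rng):
        _, cohort = self._cohort(model, configs)
        synth = SynthConfig(resolution_mix=(0.0, 1.0, 0.0))
        out = mask_resolution(cohort, synth, rng)
        assert not out.hla_1.str.contains(":").any()
        assert not out.hla_2.str.contains(":").any()

    def test_mixed_collapses_exactly_one_slot(self, model, configs, rng):
        _, cohort = self._cohort(model, configs)
        synth = SynthConfig(resolution_mix=(0.0, 0.0, 1.0))
        out = mask_resolution(cohort, synth, rng)
        collapsed_1 = (out.hla_1 != out.hla_true_1).to_numpy()
        collapsed_2 = (out.hla_2 != out.hla_true_2).to_numpy()
        # exactly one slot touched per person (a no-op collapse can only
        # happen when the true allele was already two-digit)
        touched = collapsed_1.astype(int) + collapsed_2.astype(int)
        assert touched.max() <= 1
        four_digit_both = (
            out.hla_true_1.str.contains(":") & out.hla_true_2.str.contains(":")
        ).to_numpy()
        # among people with two four-digit alleles, the chosen slot collapses
        chosen_collapsed = touched[four_digit_both]
        assert (chosen_collapsed == 1).mean() > 0.95


class TestOnsetAges:
    def test_null_hazard_matches_baseline_weibull(self, rng):
        """hr's = 1: onset ages are iid baseline Weibull (KS test)."""
        synth = SynthConfig(hr_per_or_unit=1.0, hr_smoking=1.0)
        cohort = pd.DataFrame(
            {"status": ["case"] * 5000, "ever_smoker": [0.0] * 5000}
        )
        ages = generate_onset_ages(cohort, np.ones(5000), synth, rng)
        ks = stats.kstest(
            ages.to_numpy(),
            stats.weibull_min(c=synth.weibull_shape, scale=synth.weibull_scale).cdf,
        )
        assert ks.pvalue > 0.01

    def test_protective_smoking_delays_onset(self, rng):
        synth = SynthConfig(hr_per_or_unit=1.0, hr_smoking=0.848)
        n = 10_000
        smoke = (rng.random(n) < 0.5).astype(float)
        cohort = pd.DataFrame({"status": ["case"] * n, "ever_smoker": smoke})
        ages = generate_onset_ages(cohort, np.ones(n), synth, rng).to_numpy()
        assert np.median(ages[smoke == 1]) > np.median(ages[smoke == 0])

    def test_controls_get_nan_and_draws_deterministic(self):
        synth = SynthConfig()
        cohort = pd.DataFrame(
            {"status": ["case", "control"], "ever_smoker": [1.0, 0.0]}
        )
        a = generate_onset_ages(cohort, np.array([2.0, 1.0]), synth,
                                np.random.default_rng(7))
        b = generate_onset_ages(cohort, np.array([2.0, 1.0]), synth,
                                np.random.default_rng(7))
        assert np.isnan(a.iloc[1]) and np.isnan(b.iloc[1])
        assert a.iloc[0] == b.iloc[0]


class TestMissingness:
    def _cohort(self, n=10_000):
        return pd.DataFrame(
            {
                "ever_smoker": np.ones(n),
                "rsX": np.ones(n),
                "hla_1": ["*04:01"] * n,
                "hla_2": ["*03"] * n,
            }
        )

    def test_rate_zero_unchanged(self, rng):
        synth = SynthConfig(miss_smoking=0.0, miss_snp=0.0, miss_hla=0.0)
        cohort = self._cohort(100)
        out = inject_missingness(cohort, synth, rng, snp_ids=["rsX"])
        pd.testing.assert_frame_equal(out, cohort)

    def test_rate_one_all_missing(self, rng):
        synth = SynthConfig(miss_smoking=1.0, miss_snp=1.0, miss_hla=1.0)
        out = inject_missingness(self._cohort(100), synth, rng, snp_ids=["rsX"])
        assert out.ever_smoker.isna().all()
        assert out.rsX.isna().all()
        assert out.hla_1.isna().all()

    def test_realised_rate_within_binomial_tolerance(self, rng):
        synth = SynthConfig(miss_smoking=0.2)
        out = inject_missingness(self._cohort(10_000), synth, rng)
        rate = out.ever_smoker.isna().mean()
        assert rate == pytest.approx(0.2, abs=3 * math.sqrt(0.2 * 0.8 / 10_000))


class TestEndToEnd:
    def test_scoring_synthetic_cohort_discriminates(self, model, configs):
        """Scoring a cohort generated under the HLA model yields AUC > 0.5."""
        synth = SynthConfig(n_cases=400, n_controls=400)
        cohort = generate_cohort(model, configs["HLA"], synth, seed=44)
        pop = simulate_population(configs["HLA"], model, seed=44)
        risks = score_cohort(cohort, configs["HLA"], model, build_categoriser(pop))
        cases = risks.loc[risks.status == "case", "log_or"].to_numpy()
        controls = risks.loc[risks.status == "control", "log_or"].to_numpy()
        r = roc_auc(cases, controls)
        assert r.ci_low > 0.5
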