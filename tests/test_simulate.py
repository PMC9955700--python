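"""ACE liability-threshold generator: calibration, oracles, determinism."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from twinpain.datamodel import Tristate, Zygosity, classify_cohort, write_cohort
from twinpain.similarity import (
    casewise_concordance,
    double_entry,
    phi_correlation,
    tabulate_pairs,
)
from twinpain.simulate import (
    ACEConfig,
    ConfigError,
    default_study_config,
    plant_cross_trait_effect,
    simulate_cohort,
    theoretical_similarity,
)


def twins_only(**kw):
    base = dict(sibling_rate=0.0, mother_rate=0.0, father_rate=0.0)
    base.update(kw)
    return ACEConfig(**base)


class TestConfigValidation:
    def test_variance_shares_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            ACEConfig(a2=0.5, c2=0.5, e2=0.5)

    def test_prevalence_bounds(self):
        with pytest.raises(ConfigError):
            ACEConfig(prevalence={"lbp_life": {"offspring": 1.2, "mother": 0.4,
                                               "father": 0.4}})

    def test_infeasible_trait_matrix_rejected(self):
        # three mutually strongly negative correlations cannot coexist
        extra = {
            frozenset({"lbp_life", "tlbp_current"}): -0.9,
            frozenset({"lbp_life", "migraine"}): -0.9,
            frozenset({"tlbp_current", "migraine"}): -0.9,
        }
        with pytest.raises(ConfigError, match="positive semi-definite"):
            ACEConfig(extra_corr=extra)

    def test_familial_correlations(self):
        cfg = ACEConfig(a2=0.5, c2=0.1, e2=0.4)
        assert cfg.mz_liability_correlation == pytest.approx(0.6)
        assert cfg.dz_liability_correlation == pytest.approx(0.35)
        R = cfg.family_correlation(Zygosity.DZ)
        assert R[0, 1] == pytest.approx(0.35)  # DZ co-twins
        assert R[0, 2] == pytest.approx(0.35)  # twin-sibling
        assert R[0, 3] == pytest.approx(0.25)  # parent-offspring
        assert R[3, 4] == 0.0  # parents unrelated


class TestDeterminism:
    def test_same_seed_gives_byte_identical_csv(self, tmp_path):
        cfg = twins_only(n_families=150, seed=99)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(simulate_cohort(cfg), p1)
        write_cohort(simulate_cohort(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(simulate_cohort(twins_only(n_families=150, seed=1)), p1)
        write_cohort(simulate_cohort(twins_only(n_families=150, seed=2)), p2)
        assert p1.read_bytes() != p2.read_bytes()


class TestCalibration:
    def test_realized_prevalences_match_targets(self):
        """Realized margins sit within 3 binomial SEs of their targets."""
        cfg = default_study_config(n_families=4000, seed=7)
        cohort = classify_cohort(simulate_cohort(cfg))
        checks = [
            (("twin1", "twin2"), "lbp_life", cfg.prevalence["lbp_life"]["offspring"]),
            (("twin1", "twin2"), "tlbp_current",
             cfg.prevalence["tlbp_current"]["offspring"]),
            (("mother",), "lbp_life", cfg.prevalence["lbp_life"]["mother"]),
            (("father",), "tlbp_current", cfg.prevalence["tlbp_current"]["father"]),
        ]
        from twinpain.datamodel import Role

        for roles, trait, q in checks:
            members = cohort.by_role(*(Role(r) for r in roles))
            vals = [getattr(r, trait) for r in members]
            n = sum(v is not Tristate.MISSING for v in vals)
            cases = sum(v is Tristate.CASE for v in vals)
            se = math.sqrt(q * (1 - q) / n)
            assert abs(cases / n - q) <= 3 * se, (trait, roles, cases / n, q)

    def test_mz_more_similar_than_dz_across_seeds(self):
        cfg0 = twins_only(a2=0.5, c2=0.1, e2=0.4, n_families=4000, age_log_or={})
        for seed in range(5):
            cohort = classify_cohort(simulate_cohort(
                ACEConfig(**{**cfg0.__dict__,
                             "seed": seed,
                             "prevalence": cfg0.prevalence,
                             "extra_corr": cfg0.extra_corr})))
            phis = {}
            for z in (Zygosity.MZ, Zygosity.DZ):
                counts = tabulate_pairs(cohort, "lbp_life", z)
                phis[z] = phi_correlation(double_entry(counts)).estimate
            assert phis[Zygosity.MZ] > phis[Zygosity.DZ]

    def test_no_familial_variance_gives_concordance_near_prevalence(self):
        q = 0.3
        prev = {t: dict(v) for t, v in ACEConfig().prevalence.items()}
        prev["lbp_life"]["offspring"] = q
        cfg = twins_only(a2=0.0, c2=0.0, e2=1.0, n_families=6000,
                         prevalence=prev, age_log_or={})
        cohort = classify_cohort(simulate_cohort(cfg))
        for z in (Zygosity.MZ, Zygosity.DZ):
            counts = tabulate_pairs(cohort, "lbp_life", z)
            est = casewise_concordance(counts)
            assert abs(est.estimate - q) <= 3 * math.sqrt(est.variance)

    def test_missingness_mask_drops_pairs(self):
        cfg = twins_only(n_families=500, missing_rate=0.3, seed=5)
        cohort = classify_cohort(simulate_cohort(cfg))
        counts = tabulate_pairs(cohort, "lbp_life", Zygosity.DZ)
        n_dz = sum(1 for t1, _ in cohort.twin_pairs()
                   if t1.zygosity is Zygosity.DZ)
        assert counts.total < n_dz  # some pairs lost to missingness
        assert counts.total > 0


class TestTheoreticalOracle:
    def test_independence_identity(self):
        cfg = twins_only(a2=0.0, c2=0.0, e2=1.0, age_log_or={})
        th = theoretical_similarity(cfg, Zygosity.MZ)
        q = cfg.prevalence["lbp_life"]["offspring"]
        assert th.concordance == pytest.approx(q, abs=1e-6)
        assert th.phi == pytest.approx(0.0, abs=1e-6)
        assert th.odds_ratio == pytest.approx(1.0, abs=1e-4)

    def test_perfect_correlation_identity(self):
        cfg = twins_only(a2=1.0, c2=0.0, e2=0.0, age_log_or={})
        th = theoretical_similarity(cfg, Zygosity.MZ)
        assert th.concordance == pytest.approx(1.0, abs=1e-5)

    def test_orthant_probability_vs_direct_monte_carlo(self, rng):
        """Closed-form cells agree with brute-force bivariate-normal draws."""
        q, r, n = 0.12, 0.6, 2_000_000
        t = norm.isf(q)
        z1 = rng.standard_normal(n)
        z2 = r * z1 + math.sqrt(1 - r * r) * rng.standard_normal(n)
        both = np.sum((z1 > t) & (z2 > t))
        p11_mc = both / n
        mc_se = math.sqrt(p11_mc * (1 - p11_mc) / n)
        prev = {tname: dict(v) for tname, v in ACEConfig().prevalence.items()}
        prev["lbp_life"]["offspring"] = q
        cfg = twins_only(a2=r, c2=0.0, e2=1 - r, prevalence=prev, age_log_or={})
        th = theoretical_similarity(cfg, Zygosity.MZ)
        assert abs(th.concordance * q - p11_mc) <= 3 * mc_se

    def test_phi_attenuated_below_liability_correlation(self):
        for q in (0.05, 0.12, 0.3):
            prev = {tname: dict(v) for tname, v in ACEConfig().prevalence.items()}
            prev["lbp_life"]["offspring"] = q
            for r in (0.2, 0.5, 0.8):
                cfg = twins_only(a2=r, c2=0.0, e2=1 - r, prevalence=prev,
                                 age_log_or={})
                th = theoretical_similarity(cfg, Zygosity.MZ)
                assert 0 < th.phi < r

    def test_shared_age_inflates_effective_twin_correlation(self):
        base = twins_only(a2=0.5, c2=0.1, e2=0.4, age_log_or={})
        aged = twins_only(a2=0.5, c2=0.1, e2=0.4)
        th0 = theoretical_similarity(base, Zygosity.MZ)
        th1 = theoretical_similarity(aged, Zygosity.MZ)
        assert th1.liability_correlation > th0.liability_correlation


class TestPlantedEffects:
    def test_target_one_means_zero_loading(self):
        cfg = plant_cross_trait_effect(twins_only(), ("lbp_life", "migraine"), 1.0)
        r = cfg.extra_corr[frozenset({"lbp_life", "migraine"})]
        assert abs(r) < 1e-6

    def test_planted_or_three_recovered_in_crosstab(self):
        loadings = {t: 0.0 for t in ACEConfig().factor_loadings}
        prev = {tname: dict(v) for tname, v in ACEConfig().prevalence.items()}
        prev["lbp_life"]["offspring"] = 0.12
        prev["tlbp_current"]["offspring"] = 0.10
        cfg = twins_only(n_families=50_000, factor_loadings=loadings,
                         prevalence=prev, age_log_or={}, seed=13)
        cfg = plant_cross_trait_effect(cfg, ("lbp_life", "tlbp_current"), 3.0)
        cohort = classify_cohort(simulate_cohort(cfg))
        a = b = c = d = 0
        for r in cohort.records:
            x = r.lbp_life is Tristate.CASE
            y = r.tlbp_current is Tristate.CASE
            a += x and y
            b += (not x) and y
            c += x and not y
            d += (not x) and (not y)
        or_hat = a * d / (b * c)
        se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(math.log(or_hat) - math.log(3.0)) <= 3 * se_log

    def test_extreme_target_reproduces_anchor_magnitude(self):
        """The positive-control anchor (OR 17.7) is representable."""
        cfg = default_study_config(n_families=30_000, seed=3,
                                   sibling_rate=0.0, mother_rate=0.0,
                                   father_rate=0.0, age_log_or={})
        cohort = classify_cohort(simulate_cohort(cfg))
        a = b = c = d = 0
        for r in cohort.records:
            x = r.lbp_life is Tristate.CASE
            y = r.tlbp_current is Tristate.CASE
            a += x and y
            b += (not x) and y
            c += x and not y
            d += (not x) and (not y)
        or_hat = a * d / (b * c)
        assert 17.7 * 0.7 <= or_hat <= 17.7 * 1.3

    def test_unattainable_target_raises(self):
        with pytest.raises(ConfigError, match="unattainable"):
            plant_cross_trait_effect(twins_only(), ("lbp_life", "tlbp_current"),
                                     10_000.0)
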