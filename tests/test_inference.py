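"""Bayesian inference: conjugate oracles, symmetries, calibration."""

import numpy as np
import pytest
from scipy.stats import beta, kstest

from aipower import (
    FitSettings,
    Scenario,
    decide,
    evidence_between,
    evidence_within,
    fit_experiment,
)
from aipower.simulate import ExperimentData, ReplicateCounts

from conftest import run_evidence


def make_experiment(cond1, cond2):
    return ExperimentData(
        tuple(ReplicateCounts(*t) for t in cond1),
        tuple(ReplicateCounts(*t) for t in cond2),
    )


NO_DISPERSION = FitSettings(dispersion="none")


class TestConjugateOracle:
    """Single replicate, no-overdispersion limit: the posterior must match
    the closed-form conjugate Beta posterior of a binomial proportion."""

    def test_posterior_matches_beta_when_mapping_equal(self):
        exp = make_experiment([(70, 30, 20)], [(50, 50, 30)])
        post = fit_experiment(exp, 0.8, 0.8, NO_DISPERSION)
        oracle = beta(71, 31)
        assert post.mean(1) == pytest.approx(oracle.mean(), abs=1e-3)
        assert post.tail_prob(1) == pytest.approx(oracle.cdf(0.5), rel=0.05)
        got = post.quantile(1, [0.025, 0.5, 0.975])
        want = oracle.ppf([0.025, 0.5, 0.975])
        assert np.allclose(got, want, atol=2e-3)

    def test_evidence_matches_transformed_null_tail_unequal_mapping(self):
        """With r_g1 != r_g2 the balance point maps to
        q0 = r_g1 / (r_g1 + r_g2) on the read-probability scale."""
        x, y = 300, 200
        exp = make_experiment([(x, y, 0)], [(y, x, 0)])
        post = fit_experiment(exp, 0.8, 0.6, NO_DISPERSION)
        q0 = 0.8 / (0.8 + 0.6)
        tail = beta(x + 1, y + 1).cdf(q0)
        oracle = 2 * min(tail, 1 - tail)
        assert evidence_within(post, 1) == pytest.approx(oracle, abs=0.01)


class TestFitBehaviour:
    def test_balanced_large_data_centres_on_half(self):
        exp = make_experiment([(1000, 1000, 500)] * 3, [(1000, 1000, 500)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        assert post.mean(1) == pytest.approx(0.5, abs=0.02)
        assert post.mean(2) == pytest.approx(0.5, abs=0.02)

    def test_allele_swap_maps_theta_to_complement(self):
        exp = make_experiment([(70, 30, 25), (65, 40, 20), (80, 25, 30)],
                              [(50, 55, 25), (60, 45, 20), (40, 50, 30)])
        p = fit_experiment(exp, 0.8, 0.7)
        p_sw = fit_experiment(exp.swap_alleles(), 0.7, 0.8)
        q = p.quantile(1, [0.1, 0.5, 0.9])
        q_sw = p_sw.quantile(1, [0.9, 0.5, 0.1])
        assert np.allclose(q, 1.0 - q_sw, atol=2e-3)

    def test_allele_swap_invariance_of_evidence(self):
        exp = make_experiment([(70, 30, 25), (65, 40, 20), (80, 25, 30)],
                              [(50, 55, 25), (60, 45, 20), (40, 50, 30)])
        p = fit_experiment(exp, 0.8, 0.7)
        p_sw = fit_experiment(exp.swap_alleles(), 0.7, 0.8)
        for c in (1, 2):
            assert evidence_within(p, c) == pytest.approx(
                evidence_within(p_sw, c), abs=1e-3)
        assert evidence_between(p) == pytest.approx(
            evidence_between(p_sw), abs=1e-3)

    def test_condition_swap_invariance_of_between_evidence(self):
        exp = make_experiment([(70, 30, 25), (65, 40, 20)],
                              [(50, 55, 25), (60, 45, 20)])
        p = fit_experiment(exp, 0.8, 0.8)
        p_sw = fit_experiment(exp.swap_conditions(), 0.8, 0.8)
        assert evidence_between(p) == pytest.approx(
            evidence_between(p_sw), abs=1e-6)

    def test_zero_informative_replicate_dropped_with_warning(self, caplog):
        exp = make_experiment([(70, 30, 25), (0, 0, 40)], [(50, 50, 25)])
        with caplog.at_level("WARNING", logger="aipower.inference"):
            post = fit_experiment(exp, 0.8, 0.8)
        assert "dropped 1 replicate" in caplog.text
        assert not post.flagged

    def test_all_zero_informative_reads_is_an_error(self):
        exp = make_experiment([(0, 0, 40)], [(50, 50, 25)])
        with pytest.raises(ValueError, match="no informative reads"):
            fit_experiment(exp, 0.8, 0.8)

    def test_one_sided_zero_counts_are_valid(self):
        exp = make_experiment([(30, 0, 5), (28, 2, 4)], [(15, 15, 5)] * 2)
        post = fit_experiment(exp, 0.8, 0.8)
        assert not post.flagged
        assert post.mean(1) > 0.8

    def test_posterior_draws_follow_marginal(self, rng):
        exp = make_experiment([(70, 30, 25)] * 3, [(50, 50, 25)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        draws = post.sample(4000, rng)
        assert np.all((draws["theta1"] > 0) & (draws["theta1"] < 1))
        assert draws["theta1"].mean() == pytest.approx(post.mean(1), abs=0.01)
        assert post.diagnostics["ess_draws"] >= 400


class TestEvidence:
    def test_symmetric_posterior_gives_evidence_one(self):
        exp = make_experiment([(100, 100, 50)] * 3, [(100, 100, 50)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        assert evidence_within(post, 1) == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_tail_gives_evidence_zero(self):
        exp = make_experiment([(200, 10, 40)] * 3, [(100, 100, 50)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        assert evidence_within(post, 1) < 1e-6

    def test_strong_imbalance_rejected(self):
        exp = make_experiment([(70, 30, 25)] * 3, [(50, 50, 25)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        assert evidence_within(post, 1) < 0.05

    def test_identical_conditions_give_evidence_near_one(self):
        exp = make_experiment([(60, 40, 20)] * 3, [(60, 40, 20)] * 3)
        post = fit_experiment(exp, 0.8, 0.8)
        assert evidence_between(post) > 0.95

    @pytest.mark.parametrize("evidence, level, expected", [
        (0.049, 0.05, True),
        (0.05, 0.05, False),  # strict inequality at the boundary
        (1.0, 0.05, False),
    ])
    def test_decision_rule(self, evidence, level, expected):
        assert decide(evidence, level) is expected


class TestOperatingCharacteristics:
    def test_evidence_decreases_with_imbalance(self):
        """Median within-condition evidence is non-increasing in |theta-0.5|."""
        medians = []
        for i, theta in enumerate([0.5, 0.55, 0.6, 0.65]):
            case = "a" if theta == 0.5 else "b"
            s = Scenario(n_sim=60, n_bioreps=4, theta1=0.5, theta2=theta,
                         n_reads_total=480, case=case, seed=301 + i)
            _, e2, _ = run_evidence(s)
            medians.append(np.median(e2))
        slack = 0.12  # Monte-Carlo wiggle on a median of 60 draws
        assert all(m2 <= m1 + slack for m1, m2 in zip(medians, medians[1:]))
        assert medians[-1] < medians[0]

    def test_null_evidence_near_uniform_when_replication_rich(self):
        """With many replicates the dispersion is well determined and the
        null evidence distribution approaches uniformity; this is what makes
        'evidence < 0.05' behave like a ~5% test."""
        s = Scenario(n_sim=500, n_bioreps=12, theta1=0.5, theta2=0.5,
                     n_reads_total=120, case="a", seed=77)
        e1, _, _ = run_evidence(s)
        assert kstest(e1, "uniform").statistic < 0.1
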