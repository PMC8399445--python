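import hashlib

import numpy as np
import pandas as pd
import pytest

from epimediate.simulate import (
    SimConfig,
    SimulationError,
    monte_carlo_effects,
    population_prevalence,
    simulate_cohort,
    write_fixture,
)


class TestSimConfig:
    def test_rejects_oversized_sample(self):
        with pytest.raises(ValueError, match="n_population"):
            SimConfig(seed=1, n_population=100, n_cases=80, n_controls=80)

    def test_rejects_nonpositive_sigma2(self):
        with pytest.raises(ValueError, match="sigma2"):
            SimConfig(seed=1, sigma2=0.0)

    def test_rejects_too_many_planted_pairs(self):
        with pytest.raises(ValueError, match="planted"):
            SimConfig(seed=1, p_probes=3, q_metabolites=3, n_causal_pairs=4)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(seed=7, n_causal_pairs=2, beta1=-0.5, theta_cov=(0.1, 0, 0, 0))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SimConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_yaml_without_seed_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("population:\n  n_population: 100\n")
        with pytest.raises(ValueError, match="seed"):
            SimConfig.from_yaml(tmp_path / "c.yaml")


class TestGroundTruth:
    def test_all_null_coefficients_give_null_nie(self):
        cfg = SimConfig(seed=1, theta1=0.0, theta2=0.0, theta3=0.0, beta1=0.0,
                        theta0=-3.0, n_population=4000, n_cases=30, n_controls=30,
                        p_probes=5, q_metabolites=5, n_causal_pairs=2)
        truth = simulate_cohort(cfg).truth
        assert (truth["log_nie"] == 0).all()

    def test_no_exposure_mediator_path_gives_null_nie(self):
        cfg = SimConfig(seed=2, beta1=0.0, theta2=0.5, n_population=6000,
                        n_cases=30, n_controls=30, p_probes=5, q_metabolites=5,
                        n_causal_pairs=2)
        truth = simulate_cohort(cfg).truth
        assert (truth["log_nie"] == 0).all()

    def test_worked_example_closed_form(self):
        # theta=(-4, 0.3, 0.4, 0.2), beta=(0, -0.6), sigma2=0.8:
        # log NIE = (0.4*-0.6 + 0.2*-0.6)*1 = -0.36
        cfg = SimConfig(seed=3, theta0=-4.0, theta1=0.3, theta2=0.4, theta3=0.2,
                        theta_cov=(0, 0, 0, 0), beta0=0.0, beta1=-0.6,
                        beta_cov=(0, 0, 0, 0), sigma2=0.8,
                        n_population=20_000, n_cases=50, n_controls=50,
                        p_probes=3, q_metabolites=3, n_causal_pairs=1)
        truth = simulate_cohort(cfg).truth
        assert truth["log_nie"].iloc[0] == pytest.approx(-0.36, abs=1e-12)

    def test_truth_decomposition_exact(self, small_cohort):
        _, cohort = small_cohort
        t = cohort.truth
        assert np.allclose(t["log_te"], t["log_nde"] + t["log_nie"], atol=1e-15)

    def test_closed_form_agrees_with_potential_outcome_oracle(self):
        # rare outcome: simulate counterfactual mediators and outcomes from
        # the generating models and compare odds ratios directly
        theta = (-6.0, 0.3, 0.4, 0.2)
        beta = (0.0, -0.6)
        mc = monte_carlo_effects(theta, beta, sigma2=0.8, n_draws=2_000_000, seed=17)
        assert abs(mc["log_nie"] - (-0.36)) < 3 * mc["se_log_nie"]
        closed_nde = (0.3 + 0.2 * (0.0 + 0.4 * 0.8)) * 1 + 0.5 * 0.2**2 * 0.8
        assert abs(mc["log_nde"] - closed_nde) < 3 * mc["se_log_nde"]

    def test_reverse_direction_planted_symmetrically(self):
        cfg = SimConfig(seed=9, n_population=8000, n_cases=40, n_controls=40,
                        p_probes=6, q_metabolites=6, n_causal_pairs=1,
                        n_causal_pairs_reverse=2)
        truth = simulate_cohort(cfg).truth
        assert list(truth["direction"]) == ["dnam_psv", "met_psv", "met_psv"]
        assert truth["log_nie"].nunique() == 1


class TestCohortStructure:
    def test_fixed_seed_bit_reproducible(self):
        cfg = SimConfig(seed=31, n_population=3000, n_cases=25, n_controls=25,
                        p_probes=10, q_metabolites=8, n_causal_pairs=2, theta0=-3.5)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.meth_psv.values, b.meth_psv.values)
        pd.testing.assert_frame_equal(a.met_sv.values, b.met_sv.values)
        pd.testing.assert_frame_equal(a.meta.table, b.meta.table)

    def test_exact_case_control_counts(self, small_cohort):
        cfg, cohort = small_cohort
        case = cohort.meta.case
        assert case.sum() == cfg.n_cases
        assert (case == 0).sum() == cfg.n_controls

    def test_insufficient_cases_raises_with_achieved_count(self):
        cfg = SimConfig(seed=4, theta0=-12.0, n_population=2000, n_cases=100,
                        n_controls=100, p_probes=3, q_metabolites=3, n_causal_pairs=0)
        with pytest.raises(SimulationError, match=r"realized only \d+ cases"):
            simulate_cohort(cfg)

    def test_rare_outcome_at_low_intercept(self):
        cfg = SimConfig(seed=6, theta0=-4.0, theta1=-0.4, theta2=0.4, theta3=0.2,
                        beta1=-0.6)
        assert population_prevalence(cfg, n=100_000) < 0.05

    def test_platform_batch_shift_present_in_m_values(self):
        cfg = SimConfig(seed=13, batch_shift=2.0, n_population=6000, n_cases=80,
                        n_controls=80, p_probes=50, q_metabolites=5, n_causal_pairs=0,
                        theta0=-3.0)
        cohort = simulate_cohort(cfg)
        meta = cohort.meta.table
        means = cohort.meth_psv.values.mean(axis=1)
        gap = means[meta["platform"] == "EPIC"].mean() - means[meta["platform"] == "450K"].mean()
        assert gap == pytest.approx(2.0, abs=0.2)


class TestFixtureFiles:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=8, n_population=2000, n_cases=20, n_controls=20,
                        p_probes=6, q_metabolites=4, n_causal_pairs=1, theta0=-3.0)
        digests = []
        for sub in ("a", "b"):
            paths = write_fixture(tmp_path / sub, simulate_cohort(cfg), cfg)
            digests.append(
                {k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()}
            )
        assert digests[0] == digests[1]
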