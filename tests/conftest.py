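import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests."""
    from epimediate.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        seed=11, n_population=8000, n_cases=60, n_controls=60,
        p_probes=40, q_metabolites=15, n_causal_pairs=3,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_pair_data():
    """A single strongly-planted pair at case-control n=600 for mediation tests."""
    from epimediate.mediation import PairData
    from epimediate.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        seed=5, n_population=40_000, n_cases=300, n_controls=300,
        p_probes=2, q_metabolites=2, n_causal_pairs=1,
    )
    cohort = simulate_cohort(cfg)
    cov = cohort.meta.covariate_design(include_platform=True)
    data = PairData(
        exposure=cohort.meth_psv.values["cg000000"].to_numpy(),
        mediator=cohort.met_sv.values["met0000"].to_numpy(),
        case=cohort.meta.case,
        covariates=cov.to_numpy(),
        covariate_names=tuple(cov.columns),
    )
    return cfg, cohort, data


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
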