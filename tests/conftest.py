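import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pfoa_priors():
    from qivive.priors import load_pfoa_priors

    return load_pfoa_priors()


@pytest.fixture(scope="session")
def default_params():
    from qivive.pbk import PBKParameters

    return PBKParameters()


@pytest.fixture()
def scenario():
    from qivive.pbk import ExposureScenario

    def make(**kwargs):
        return ExposureScenario(**kwargs)

    return make


@pytest.fixture(scope="session")
def ishigami_priors():
    from qivive.priors import DistributionSpec, PriorSet

    ps = PriorSet()
    for name in ("x1", "x2", "x3"):
        ps.add(DistributionSpec(name, "uniform", None, None, -np.pi, np.pi))
    return ps


def ishigami(d, a=7.0, b=0.1):
    return (
        np.sin(d["x1"]) + a * np.sin(d["x2"]) ** 2 + b * d["x3"] ** 4 * np.sin(d["x1"])
    )


#: Closed-form Ishigami variance shares for a=7, b=0.1.
def ishigami_indices(a=7.0, b=0.1):
    pi4 = np.pi**4
    v1 = 0.5 * (1 + b * pi4 / 5) ** 2
    v2 = a**2 / 8
    v13 = b**2 * pi4**2 * (1.0 / 18 - 1.0 / 50)  # x1-x3 interaction
    v = v1 + v2 + v13
    s = np.array([v1 / v, v2 / v, 0.0])
    st = np.array([(v1 + v13) / v, v2 / v, v13 / v])
    return s, st


@pytest.fixture(scope="session")
def calibrated_posterior(pfoa_priors):
    """One shared synthetic-recovery calibration run (used by several tests)."""
    from qivive import calibration as cal
    from qivive.pipeline import CALIBRATED_PARAMS, DEFAULT_CONFIG, _calibration_predict
    from qivive.synthetic import SyntheticTruth, gen_biomonitoring

    truth = SyntheticTruth(seed=5)
    data, _ = gen_biomonitoring(truth, n_per_group=10)
    priors = pfoa_priors.subset(CALIBRATED_PARAMS)
    posterior = cal.run_mcmc(
        priors,
        data,
        _calibration_predict(DEFAULT_CONFIG, data),
        iterations=3000,
        chains=4,
        seed=3,
    )
    return truth, data, priors, posterior
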