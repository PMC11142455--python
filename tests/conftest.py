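import logging

import numpy as np
import pytest

from reconfig_swm.parcellation import make_scheme, reduced_scheme
from reconfig_swm.pipeline import PipelineConfig, analyze_cohort
from reconfig_swm.synthetic import CohortSpec, simulate_cohort

logging.getLogger("reconfig_swm").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scheme30():
    return reduced_scheme(30)


@pytest.fixture(scope="session")
def scheme_full():
    return make_scheme()


@pytest.fixture(scope="session")
def tiny_spec(scheme30):
    return CohortSpec(n_young=3, n_old=3, n_rois=30, scheme=scheme30, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return simulate_cohort(tiny_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_results(tiny_spec, tiny_cohort):
    cfg = PipelineConfig(cohort=tiny_spec, within_load=True, averaged_fc_validation=True)
    return analyze_cohort(tiny_cohort, cfg, apply_filters=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
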