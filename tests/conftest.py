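import numpy as np
import pytest

from dtmdd import (DoseEvent, StructuralParams, final_model_params,
                   generate_dataset, generate_joint_dataset)
from dtmdd import designs


@pytest.fixture(scope="session")
def final_pop():
    return final_model_params()


@pytest.fixture(scope="session")
def typical_ibd(final_pop):
    """Covariate-adjusted typical female CD subject at the reference weight."""
    from dtmdd.population import SubjectCovariates, typical_params

    return typical_params(final_pop, SubjectCovariates(BW=66.0))


@pytest.fixture(scope="session")
def standard_regimen():
    """5 mg/kg x 66 kg (330 mg, unrounded) at weeks 0, 2, 6, 14, 22."""
    return [DoseEvent(7.0 * w, 330.0) for w in (0, 2, 6, 14, 22)]


@pytest.fixture(scope="session")
def linear_params():
    """Base-model two-compartment backbone (no TMDD)."""
    return StructuralParams(V1=2.8, V2=1.9, CL=0.20, Q=1.5)


@pytest.fixture(scope="session")
def small_joint_dataset(final_pop):
    """10 AS + 40 rich-IBD subjects, the workhorse estimation fixture."""
    return generate_joint_dataset(final_pop, 10, 40, seed=7,
                                  ibd_design=designs.IBD_RICH)


@pytest.fixture(scope="session")
def sparse_ibd_dataset(final_pop):
    return generate_dataset(designs.IBD_SPARSE, final_pop, 60, seed=11)
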