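import numpy as np
import pytest

from mechanoclock import (CircadianParams, MechanoParams, TreatmentCondition,
                          sample_parameters, simulate_population)


@pytest.fixture(scope="session")
def mech():
    return MechanoParams()


@pytest.fixture(scope="session")
def circ():
    return CircadianParams()


COHORT_CONDITIONS = {
    "soft": TreatmentCondition(substrate_stiffness=0.1, label="soft"),
    "glass": TreatmentCondition(label="glass"),
    "wt30": TreatmentCondition(substrate_stiffness=30.0, label="wt30"),
    "yap5sa30": TreatmentCondition(substrate_stiffness=30.0,
                                   mutation="YAP_5SA", label="yap5sa30"),
    "lmna30": TreatmentCondition(substrate_stiffness=30.0, mutation="LMNA",
                                 label="lmna30"),
    "yap5sa_rescue": TreatmentCondition(substrate_stiffness=0.3,
                                        mutation="YAP_5SA",
                                        label="yap5sa_rescue"),
    "lmna_rescue": TreatmentCondition(substrate_stiffness=3.0,
                                      mutation="LMNA", label="lmna_rescue"),
}

COHORT_SEED = 42


@pytest.fixture(scope="session")
def cohorts(mech, circ):
    """200-cell cohorts for the population-level acceptance checks.

    Computed once per session (the DDE solves are vectorized across cells);
    shared by the directional and rescue tests.
    """
    out = {}
    for name, cond in COHORT_CONDITIONS.items():
        sets = sample_parameters(mech, circ, 200, seed=COHORT_SEED)
        out[name] = simulate_population(sets, cond, seed=COHORT_SEED + 1)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
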