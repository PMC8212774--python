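import numpy as np
import pandas as pd
import pytest

import fosfopk as fp


@pytest.fixture(scope="session")
def ref_pop():
    return fp.reference_parameters()


@pytest.fixture(scope="session")
def adult_reference(ref_pop):
    """Typical fully mature 70 kg individual parameters."""
    cov = fp.SubjectCovariates(weight=70.0, postnatal_age=1e5, postmenstrual_age=1e5)
    return fp.individual_typical_parameters(ref_pop, cov)


@pytest.fixture(scope="session")
def median_neonate(ref_pop):
    """The trial's median baby: 2.805 kg, PMA 40.1 weeks, PNA 1 day."""
    cov = fp.SubjectCovariates(weight=2.805, postnatal_age=1.0, gestational_age=40.0)
    return fp.individual_typical_parameters(ref_pop, cov)


def rich_iv_design(covs, sample_times=(0.25, 0.5, 1, 2, 4, 6, 8, 10)):
    """Single-IV-dose design with dense plasma sampling per subject."""
    rows = []
    for i, c in enumerate(covs, 1):
        base = dict(
            ID=i, WT=c.weight, GA=c.gestational_age, PNA=c.postnatal_age,
            PMA=c.postmenstrual_age,
        )
        rows.append(dict(base, TIME=0.0, AMT=100 * c.weight, EVID=1, MDV=1, CMT=2, ROUTE="iv"))
        for t in sample_times:
            rows.append(dict(base, TIME=float(t), EVID=0, MDV=0, CMT=2))
    return fp.EventTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_rich_cohort(ref_pop):
    """Two subjects with rich IV sampling, one eta (CL): quadrature-sized."""
    rng = np.random.default_rng(7)
    demo = fp.sample_neofosfo_demographics(2, rng)
    design = rich_iv_design(demo)
    pop = ref_pop.with_updates(omega_v2=0.0, omega_f=0.0)
    sim = fp.simulate_cohort(pop, demo, design, seed=3)
    return pop, sim


@pytest.fixture(scope="session")
def small_trial(ref_pop):
    """A 12-subject sparse cross-over trial simulated under the model."""
    rng = np.random.default_rng(101)
    demo = fp.sample_neofosfo_demographics(12, rng)
    trial = fp.make_trial(demo, rng)
    sim = fp.simulate_cohort(ref_pop, demo, trial, seed=rng)
    return demo, trial, sim
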