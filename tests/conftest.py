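import numpy as np
import pytest

from dlw import DosePrep, IsotopeCurve, KineticParams, SubjectRecord
from dlw import core
from dlw.constants import ModelConstants
from dlw.simulate import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def constants() -> ModelConstants:
    return ModelConstants()


@pytest.fixture
def dose() -> DosePrep:
    return DosePrep(D=80.0, d=1.0, T=250.0, delta_dd=700.0, delta_T=-50.0)


def make_subject(kin: KineticParams, W=70.0, noise=(0.0, 0.0), seed=0,
                 times=None, basal=(-46.0, -7.0)) -> SubjectRecord:
    """Forward-simulate a subject directly from kinetics (no population draw)."""
    rng = np.random.default_rng(seed)
    times = np.arange(1.0, 15.0) if times is None else np.asarray(times, float)
    doses, curves = {}, {}
    for iso, N, k, db, sd, excess0 in (("2H", kin.N_H, kin.k_H, basal[0], noise[0], 350.0),
                                       ("18O", kin.N_O, kin.k_O, basal[1], noise[1], 120.0)):
        d = DosePrep(D=80.0, d=1.0, T=250.0,
                     delta_dd=db + excess0 * 18.02 * N / (80.0 * 250.0), delta_T=db)
        y = core.enrichment_at(times, d, N, k, db)
        if sd > 0:
            y = y + sd * rng.standard_normal(times.size)
        doses[iso] = d
        curves[iso] = IsotopeCurve(isotope=iso, times=times, delta_values=y, delta_b=db)
    return SubjectRecord(id="T1", sex="M", weight=W, doses=doses, curves=curves)


@pytest.fixture
def textbook_kin() -> KineticParams:
    return KineticParams(N_H=2526.0, N_O=2446.0, k_H=0.0838, k_O=0.1098)


@pytest.fixture
def noisefree_subject(textbook_kin) -> SubjectRecord:
    return make_subject(textbook_kin)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject synthetic cohort at the default noise levels."""
    design = CohortDesign(n_women=3, n_men=3, seed=101)
    return simulate_cohort(design)
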