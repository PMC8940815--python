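import numpy as np
import pytest

from pulmodeconv.models import AbsorptionVariant, ParameterSet, VariantName
from pulmodeconv.simulate import (
    Occasion,
    StudyArm,
    TrialDesign,
    VariabilityModel,
    single_dose_occasion,
)
from pulmodeconv.models import Route

IDENTIFIABLE_VARIANTS = ["I", "II", "IIIa", "Transit"]
ALL_ONE_DIRECTIONAL = ["I", "II", "IIIa", "IIIb", "Transit", "NaL"]


@pytest.fixture
def disposition_2cmt() -> dict:
    return dict(cl=30.0, v1=20.0, q2=20.0, v2=100.0)


@pytest.fixture
def model_ii(disposition_2cmt):
    """A well-separated two-process model (both processes visible in plasma)."""
    variant = AbsorptionVariant.from_name(VariantName.II)
    params = ParameterSet(**disposition_2cmt, f_pul=0.4, f_fast=0.7,
                          k_fast=1.5, f_slow=0.3, k_slow=0.1)
    return variant, params


@pytest.fixture
def model_i(disposition_2cmt):
    variant = AbsorptionVariant.from_name(VariantName.I)
    params = ParameterSet(**disposition_2cmt, f_pul=0.5, k_fast=0.1)
    return variant, params


@pytest.fixture
def small_crossover_design():
    """Tiny cross-over design used by the NLME strategy tests."""
    sampling = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0, 48.0)
    return TrialDesign(
        arms=(
            StudyArm(Route.IV, 8, (single_dose_occasion(50.0, sampling),)),
            StudyArm(Route.INHALED, 8, (single_dose_occasion(200.0, sampling),)),
        ),
        crossover=True,
    )


@pytest.fixture
def mild_variability():
    return VariabilityModel(iiv={"cl": 0.2, "f_pul": 0.2},
                            residual_proportional_sd=0.1)
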