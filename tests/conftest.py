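import pytest

from biopsyreduce import (
    CovariateVector,
    LesionLocation,
    SyntheticConfig,
    generate_cohort,
    get_layout,
    make_table2_fixture,
)


@pytest.fixture(scope="session")
def layout12():
    return get_layout("changhai_12")


@pytest.fixture(scope="session")
def layout13():
    return get_layout("fujian_13")


@pytest.fixture(scope="session")
def layer1_fixture():
    """The 122-patient layer-1 count fixture (35 positive / 87 negative)."""
    return make_table2_fixture()


@pytest.fixture
def median_covariates():
    """Central covariate values of the modeling cohort, PI-RADS 4."""
    return CovariateVector(
        age=68, bmi=24.22, tpsa=10.8, transverse_diameter=4.9,
        anteroposterior_diameter=3.4, cephalocaudal_diameter=4.0,
        lesion_longest_diameter=1.5, pirads=4,
    )


@pytest.fixture
def right_base_lesion():
    return LesionLocation(side="right", level="base", zone="peripheral")


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(SyntheticConfig(n=600, seed=11))
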