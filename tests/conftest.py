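import numpy as np
import pytest

from ovascreen import Cohort, VisitSeries, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40 controls / 20 cases, three markers, fixed seed."""
    cohort, truth = generate_cohort(GeneratorConfig(n_controls=40, n_cases=20,
                                                    seed=11))
    return cohort, truth


@pytest.fixture
def tiny_cohort():
    """One control + one case, one marker: the smallest fittable instance."""
    control = VisitSeries("c0", 0, ages=[60.0, 61.0, 62.0],
                          levels={"CA125": [12.0, 13.5, 11.0]})
    case = VisitSeries("p0", 1, ages=[60.0, 61.0, 62.0],
                       levels={"CA125": [12.0, 30.0, 90.0]},
                       diagnosis_age=62.0)
    return Cohort([control, case], biomarker_names=["CA125"])
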