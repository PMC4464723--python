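import numpy as np
import pytest

from batkit import (
    CohortSpec,
    RunConfig,
    analyze_cohort,
    generate_cohort,
)
from batkit.pipeline import calibration_report


@pytest.fixture(scope="session")
def small_spec():
    """A fast, reduced cohort: peanut only, one planted violation of each
    kind, tight latent spread so every expectation is unambiguous."""
    spec = CohortSpec(seed=11).subset(groups=("PA", "PS"), allergens=("peanut",))
    return spec.subset(
        group_sizes={"PA": 6, "PS": 4},
        planted_spontaneous={"PA": 1, "PS": 0},
        planted_posctrl_nonresponders={"PA": 1, "PS": 0},
    )


@pytest.fixture(scope="session")
def small_run(small_spec):
    cohort = generate_cohort(small_spec)
    report = analyze_cohort(cohort, RunConfig(spec=small_spec, seed=small_spec.seed))
    return cohort, report


@pytest.fixture(scope="session")
def study_run():
    """One full default cohort (PA 47 / PS 22 / C 22, three allergens) at a
    fixed seed, analysed end to end."""
    spec = CohortSpec(seed=0)
    cohort = generate_cohort(spec)
    report = analyze_cohort(cohort, RunConfig(spec=spec, seed=0))
    return cohort, report


@pytest.fixture(scope="session")
def calibration_20():
    """The 20-seed calibration table of the default PA/PS peanut cohort."""
    return calibration_report(base_seed=0, n_seeds=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
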