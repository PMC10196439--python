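import numpy as np
import pytest

from ivmpbpk import GutPhysiology, load_compound, reference_adult, reference_child


@pytest.fixture(scope="session")
def ivermectin():
    return load_compound()


@pytest.fixture(scope="session")
def ref_adult():
    return reference_adult()


@pytest.fixture(scope="session")
def ref_child():
    return reference_child()


@pytest.fixture(scope="session")
def fasted_gut():
    return GutPhysiology.fasted_adult()


@pytest.fixture(scope="session")
def fed_gut():
    return GutPhysiology.fed_adult()


@pytest.fixture(scope="session")
def reference_profile_12mg(ivermectin, ref_adult):
    """Shared 12 mg fasted reference-adult simulation."""
    from ivmpbpk import build_model, simulate

    return simulate(build_model(ref_adult, ivermectin), 12.0)


@pytest.fixture(scope="session")
def tiny_trial(ivermectin):
    """A small but complete seeded virtual trial (2 trials x 3 subjects)."""
    from ivmpbpk import StudyDesign, run_trial

    design = StudyDesign(
        label="tiny", population="healthy_volunteer", n_subjects=3,
        dose_mg=12.0, n_trials=2,
    )
    return design, run_trial(design, ivermectin, seed=7)
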