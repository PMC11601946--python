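import numpy as np
import pytest

from chamberlab import calorimetry as cal
from chamberlab import qc, synthetic
from chamberlab.protocol import build_diet_library


@pytest.fixture(scope="session")
def diet_library():
    return build_diet_library()


@pytest.fixture(scope="session")
def diets_by_name(diet_library):
    return {d.name: d for d in diet_library}


@pytest.fixture(scope="session")
def study():
    """Default-size synthetic study shared across the statistical tests."""
    return synthetic.simulate_study(synthetic.SimConfig(seed=7))


@pytest.fixture(scope="session")
def study_summaries(study):
    return cal.summarize_sessions(study.traces, study.nitrogen)


@pytest.fixture(scope="session")
def study_outcomes(study_summaries):
    return study_summaries.rename(columns={
        "ee24": "EE24", "rq24": "RQ24",
        "lipox": "LIPOX", "carbox": "CARBOX", "protox": "PROTOX"})


@pytest.fixture(scope="session")
def study_qc(study):
    return qc.run_qc(study.metabolome, study.qc_replicates)


@pytest.fixture(scope="session")
def study_fold_changes(study_qc):
    filtered, _ = study_qc
    return qc.log2_fold_change(filtered)


@pytest.fixture(scope="session")
def study_covariates(study):
    return study.participants_frame()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
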