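import pytest

from renalperf import GeneratorConfig, generate_with_metadata, stage_patient


@pytest.fixture(scope="session")
def default_result():
    """One default synthetic cohort (84 patients) with generator metadata."""
    return generate_with_metadata(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_cohort(default_result):
    return default_result.cohort


@pytest.fixture(scope="session")
def default_outcomes(default_cohort):
    return {p.patient_id: stage_patient(p) for p in default_cohort}
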