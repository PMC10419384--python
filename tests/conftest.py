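import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_cohort():
    from olfact import build_paper_cohort

    return build_paper_cohort()


@pytest.fixture(scope="session")
def clinical_report():
    from olfact import reproduce_clinical

    return reproduce_clinical()
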