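import numpy as np
import pytest
from hypothesis import settings

from famred import popgen

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True, print_blob=False
)
settings.load_profile("ci")


@pytest.fixture
def unedited_profile():
    return popgen.OutcomeProfile(p_unedited=1.0, p_indel_only=0.0)


@pytest.fixture
def wt_profile():
    """Outcome spectrum of a p53-proficient editing experiment.

    Total LOH 0.18%, so the detectable (reporter-visible) fraction is 0.09%
    with unbiased homolog targeting.
    """
    return popgen.OutcomeProfile.from_loh_total(0.0018)


@pytest.fixture
def p53null_profile():
    """p53-deficient regime: total LOH 11.2%, detectable 5.6%."""
    return popgen.OutcomeProfile.from_loh_total(0.112)


@pytest.fixture
def clean_model():
    """Channel model without assay noise, for estimator-consistency checks."""
    return popgen.FlowChannelModel(
        autofluorescence_rate=0.0, background_switch_rate=0.0
    )
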