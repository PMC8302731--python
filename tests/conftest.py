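import pytest

from splice_rescue import assemble_donor_region, load_pwm


@pytest.fixture(scope="session")
def fd_region():
    return assemble_donor_region("fd")


@pytest.fixture(scope="session")
def wt_region():
    return assemble_donor_region("wt")


@pytest.fixture(scope="session")
def srsf6():
    return load_pwm("SRSF6")
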