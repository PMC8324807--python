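import pytest
from hypothesis import settings as hypothesis_settings

from besskit import DEFAULT_TEMPLATE, ReadErrorModel, enumerate_pams, generate_library_reads

hypothesis_settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def all_pams():
    return enumerate_pams(4)


@pytest.fixture(scope="session")
def uniform_unedited_reads(template, all_pams):
    """25600 noiseless unedited reads, uniform over the 256-PAM library."""
    return generate_library_reads(
        {p: 1.0 for p in all_pams},
        0.0,
        template,
        25_600,
        ReadErrorModel.noiseless(),
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_mixed_reads(template, all_pams):
    """1e4 reads at 1% substitution error with mixed editing, for oracle checks."""
    ef = {p: (0.8 if p[1:3] == "GG" else 0.05) for p in all_pams}
    return generate_library_reads(
        {p: 1.0 for p in all_pams},
        ef,
        template,
        10_000,
        ReadErrorModel(substitution_rate=0.01, n_rate=0.002, adapter_rate=0.02),
        seed=11,
    )
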