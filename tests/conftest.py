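import pytest
from hypothesis import settings

from nistrace.io import AlignedSequenceSet, load_table1_fixture

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def aligned(*seqs: str, species: str = "Test sp.", region: str = "BB") -> AlignedSequenceSet:
    """Build an alignment from bare sequence strings with generated ids."""
    return AlignedSequenceSet(
        species=species, region=region,
        sequences=[(f"s{i + 1}", s) for i, s in enumerate(seqs)],
    )


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()
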