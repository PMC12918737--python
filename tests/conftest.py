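import warnings

import pytest

from tadscan.align_core import ScoringScheme
from tadscan.synthetic_data import default_reference_set


@pytest.fixture(scope="session")
def refs():
    return default_reference_set()


@pytest.fixture(scope="session")
def nt_unit_scheme():
    """Unit match/mismatch scoring used by the hand-checkable examples."""
    return ScoringScheme.nucleotide(match=1, mismatch=-1, gap_open=2,
                                    gap_extend=1)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("default")
        yield
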