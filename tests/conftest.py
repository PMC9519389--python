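import numpy as np
import pytest

from nlrmotifs.profiles import FocusedDB
from nlrmotifs.registry import default_registry, registry_by_name
from nlrmotifs.seqio import SequenceRecord

#: A fixed 60-aa query used by the profile-search fixtures.
QUERY_SEQ = "MKVLAWDETTRSYHGGKLMNPQFICDEHWRVSTAYLKGMNDPQRFEWILSTCVHYAGKMN"


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def by_name(registry):
    return registry_by_name(registry)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def query_record():
    return SequenceRecord("query", QUERY_SEQ)


@pytest.fixture(scope="session")
def copies_db(query_record):
    """Ten exact copies of the query plus two unrelated sequences."""
    unrelated = [
        SequenceRecord("u1", "PPPPGGGGSSSSNNNNQQQQHHHHRRRRKKKKDDDDEEEE"),
        SequenceRecord("u2", "WWWWYYYYFFFFMMMMCCCCAAAAVVVVLLLLIIIITTTT"),
    ]
    copies = [
        SequenceRecord(f"copy{i}", query_record.residues) for i in range(10)
    ]
    return FocusedDB(copies + unrelated)
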