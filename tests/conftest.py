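import numpy as np
import pytest

from foldcluster.alignment import ScoringParams
from foldcluster.records import ALPHABET, StructureRecord


@pytest.fixture(scope="session")
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture(scope="session")
def aa_params() -> ScoringParams:
    return ScoringParams.aa_only()


def random_record(rng: np.random.Generator, rid: str, length: int
                  ) -> StructureRecord:
    letters = list(ALPHABET)
    return StructureRecord(
        rid,
        "".join(rng.choice(letters, size=length)),
        "".join(rng.choice(letters, size=length)),
    )
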