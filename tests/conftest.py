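import numpy as np
import pandas as pd
import pytest

from metasig.diagmeta import Diagnostic2x2
from metasig.ingest import AliasMap, StudySignature


@pytest.fixture(scope="session")
def aliases() -> AliasMap:
    return AliasMap.bundled()


@pytest.fixture
def toy_signatures() -> tuple[list[StudySignature], list[StudySignature]]:
    """Three up-lists and two down-lists over a small shared namespace."""
    up = [
        StudySignature("s1", 10, "up", ("hsa-miR-a-3p", "hsa-miR-b-5p")),
        StudySignature("s2", 20, "up", ("hsa-miR-a-3p", "hsa-miR-c-3p", "hsa-miR-d-5p")),
        StudySignature("s3", 8, "up", ("hsa-miR-b-5p", "hsa-miR-a-3p")),
    ]
    down = [
        StudySignature("s1", 10, "down", ("hsa-miR-e-3p", "hsa-miR-b-5p")),
        StudySignature("s2", 20, "down", ("hsa-miR-e-3p",)),
    ]
    return up, down


@pytest.fixture
def identical_studies() -> list[Diagnostic2x2]:
    return [Diagnostic2x2(f"s{i}", tp=8, fn=2, tn=8, fp=2) for i in range(5)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
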