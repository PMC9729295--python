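import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles as `oracles`

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phosphoscreen.io import (IntensityMatrix, PhosphoPeptideRecord,
                              SampleAnnotation)


def make_record(pid: str, window: str = "AAAAAAASAAAAAAA",
                residue: str = "S") -> PhosphoPeptideRecord:
    return PhosphoPeptideRecord(
        peptide_id=pid, protein_ids=("PROT1",), residue=residue,
        site_position=10, sequence_window=window)


@pytest.fixture
def small_matrix() -> IntensityMatrix:
    """3 peptides x 4 samples with one undetected cell."""
    peptides = [make_record(f"pep{i}") for i in range(1, 4)]
    values = np.array([
        [100.0, 200.0, 50.0, 80.0],
        [0.0, 10.0, 5.0, 7.0],
        [1e6, 2e6, 3e6, 4e6],
    ])
    return IntensityMatrix.from_records(peptides, ["s1", "s2", "s3", "s4"], values)


@pytest.fixture
def small_annotations() -> list[SampleAnnotation]:
    return [
        SampleAnnotation("s1", "standard", "responder"),
        SampleAnnotation("s2", "standard", "responder"),
        SampleAnnotation("s3", "standard", "nonresponder"),
        SampleAnnotation("s4", "standard", "nonresponder"),
    ]
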