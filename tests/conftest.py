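import numpy as np
import pytest

from fisim.io import Dataset, SequenceRecord
from fisim.markov import TransitionMatrix

TOY_SEQUENCES = ["AAAAAAAAAA", "ATATATATAT", "ACGTACGTAC"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """Three short sequences exercising degenerate and regular rows alike."""
    return Dataset([SequenceRecord(id=f"s{i + 1}", residues=seq)
                    for i, seq in enumerate(TOY_SEQUENCES)])


@pytest.fixture
def fasta_factory(tmp_path):
    """Write FASTA content to a temp file and return its path."""
    def _write(content: str, name: str = "input.fasta"):
        path = tmp_path / name
        path.write_text(content)
        return path
    return _write


@pytest.fixture
def random_transition_matrix(rng):
    def _make(step: int = 1) -> TransitionMatrix:
        p = rng.random((4, 4))
        p /= p.sum(axis=1, keepdims=True)
        return TransitionMatrix(p=p, step=step)
    return _make
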