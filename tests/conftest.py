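import numpy as np
import pytest

from hydrophobins.seqio import SequenceRecord

# EAS Delta-15: the rodlet-forming class I hydrophobin of Neurospora crassa
# (N-terminal 15 residues removed), the standard worked example for the
# canonical eight-cysteine motif.
EAS_D15 = (
    "SATTIGPNTCSIDDYKPYCCQSMSGSASLGCVVGVIGSQCGASVKCCKDDVTNTGNSFLIINAANCVA"
)


@pytest.fixture
def eas_record() -> SequenceRecord:
    return SequenceRecord(id="EAS_D15", residues=EAS_D15, class_label="class_I")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
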