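import sys
from pathlib import Path

import numpy as np
import pytest

# make tests/helpers.py importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fa"
    p.write_text(">r1\nAAGT\n>r2\nGTCC\n")
    return p
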