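import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rflkit.ppr_annotate import default_models  # noqa: E402
from rflkit.ppr_code import default_code_table  # noqa: E402


@pytest.fixture(scope="session")
def models():
    return default_models()


@pytest.fixture(scope="session")
def p_model(models):
    return next(m for m in models if m.name == "P")


@pytest.fixture(scope="session")
def code_table():
    return default_code_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_protein(rng, n):
    return "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n)])
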