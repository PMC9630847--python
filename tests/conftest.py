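import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from triadnet.synthetic_data import SimConfig, generate_expression, generate_truth


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One synthetic cohort (truth + expression) shared across tests."""
    truth = generate_truth(default_config)
    expr, mirna_expr = generate_expression(truth, default_config)
    return {"config": default_config, "truth": truth, "expr": expr, "mirna_expr": mirna_expr}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
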