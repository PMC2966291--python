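import pytest

from ngn.config import TrainingConfig, preset
from ngn.grammar import builtin_grammar
from ngn.parse import parse_string
from ngn.synthetic import SynthTask, make_dataset

ISOPENTANOL = "CC(C)CCO"
# the canonical leftmost derivation of isopentanol under the subset grammar
ISOPENTANOL_DERIVATION = [1, 3, 5, 4, 5, 7, 8, 9, 2, 5, 10, 3, 5, 3, 5, 2, 6]


@pytest.fixture(scope="session")
def subset():
    return builtin_grammar("smiles_subset")


@pytest.fixture(scope="session")
def extended():
    return builtin_grammar("smiles_extended")


@pytest.fixture(scope="session")
def inchi():
    return builtin_grammar("inchi_basic")


@pytest.fixture(scope="session")
def isopentanol_tree(subset):
    return parse_string(ISOPENTANOL, subset)


@pytest.fixture()
def small_cfg():
    """Tiny config for fast unit-level training runs."""
    return TrainingConfig(hidden_size=4, max_epochs=200, max_restarts=1, seed=0)


@pytest.fixture(scope="session")
def oxygen_dataset(subset):
    """The contains-oxygen classification benchmark dataset (n=200)."""
    task = SynthTask(kind="classification", label_rule="contains_token",
                     param="O", n=200, max_depth=14, seed=42)
    return make_dataset(task, subset)


@pytest.fixture(scope="session")
def ccount_dataset(subset):
    """The scaled-C-count regression benchmark dataset (n=150, no noise)."""
    task = SynthTask(kind="regression", label_rule="scaled_token_count",
                     param="C", n=150, max_depth=14, noise_sd=0.0, seed=7)
    return make_dataset(task, subset)


@pytest.fixture(scope="session")
def classification_cfg():
    return preset("classification")


@pytest.fixture(scope="session")
def regression_cfg():
    return preset("regression_cv")
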