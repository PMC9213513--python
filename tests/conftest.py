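import pytest

from mbondecode.config import GeneratorConfig
from mbondecode.pipeline import quantified_experiment


@pytest.fixture(scope="session")
def default_aucs():
    """Normalized AUC table of one full default synthetic experiment."""
    return quantified_experiment(GeneratorConfig(seed=7))
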