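import numpy as np
import pytest

from qpcrmlm import ModelSpec, load_example_table


@pytest.fixture
def table2():
    """The packaged 10-sample GAPDH/MMP10 CT table."""
    return load_example_table()


@pytest.fixture
def table2_spec():
    """The worked-example ANCOVA model: MMP10 ~ Donor + Treatment + GAPDH."""
    return ModelSpec(
        response="MMP10",
        treatment="Treatment",
        control_level="DMSO",
        nuisance_factors=("Donor",),
        reference_genes=("GAPDH",),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
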