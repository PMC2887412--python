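import pytest

from optorf import (build_example_network, example_environment,
                    compile_gpr, compile_regulation)


@pytest.fixture(scope="session")
def example_model():
    return build_example_network()


@pytest.fixture(scope="session")
def env10():
    """Substrate uptake up to 10 units: growth scales comfortably above the
    conventional 0.1/hr minimal-growth floor."""
    return example_environment(10.0)


@pytest.fixture(scope="session")
def env1():
    return example_environment(1.0)


@pytest.fixture(scope="session")
def example_indices(example_model):
    return compile_gpr(example_model), compile_regulation(example_model)
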