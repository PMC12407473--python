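import pytest
from hypothesis import settings

from glmpower import load_example

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def examples():
    """The five packaged example designs, loaded once."""
    return {name: load_example(name) for name in
            ("example1", "example2", "example3", "example4", "example5")}


@pytest.fixture(scope="session")
def example1(examples):
    return examples["example1"]


@pytest.fixture(scope="session")
def example2(examples):
    return examples["example2"]


@pytest.fixture(scope="session")
def example3(examples):
    return examples["example3"]


@pytest.fixture(scope="session")
def example4(examples):
    return examples["example4"]


@pytest.fixture(scope="session")
def example5(examples):
    return examples["example5"]
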