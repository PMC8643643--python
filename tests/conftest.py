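import pytest

from asescope import pipeline, synthetic_data as sd


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic bundle at generator defaults, fixed seed."""
    return sd.simulate(sd.GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return pipeline.run_pipeline(default_bundle)
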