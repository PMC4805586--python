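import pytest

from mirtol import RunConfig, default_spec, gen_expression


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def planted_study():
    """One default synthetic study, shared across read-only tests."""
    spec = default_spec(rng_seed=7)
    mirna, mrna, design, predictions, truth = gen_expression(spec)
    return {
        "spec": spec,
        "mirna": mirna,
        "mrna": mrna,
        "design": design,
        "predictions": predictions,
        "truth": truth,
    }
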