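import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")

import armshift as a


@pytest.fixture(scope="session")
def fig3a_run():
    """Noise-free nested triple inversion on group 6, end to end."""
    config = a.fig3a_scenario(7)
    model, truth = a.simulate_genome(config)
    hits = a.emit_hits(model)
    result = a.classify_all(hits, genes=list(truth["gene"]))
    return model, truth, hits, result


@pytest.fixture(scope="session")
def default_run():
    """One default-noise simulated genome with planted inversions."""
    config = a.default_scenario(11)
    model, truth = a.simulate_genome(config)
    hits = a.emit_hits(model)
    result = a.classify_all(hits, genes=list(truth["gene"]))
    gmap = a.genetic_map(model)
    calls = a.call_all(result.patterns, gmap)
    return config, model, truth, hits, result, gmap, calls
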