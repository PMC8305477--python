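import pytest

from editscan import simulate


@pytest.fixture(scope="session")
def default_config():
    return simulate.SimulationConfig()


@pytest.fixture(scope="session")
def study(default_config, tmp_path_factory):
    """The default synthetic study, generated once and written to disk."""
    out = tmp_path_factory.mktemp("study")
    genome, annotation, masks, matrix, variants, truth = \
        simulate.generate_study(default_config, out)
    return {
        "genome": genome, "annotation": annotation, "masks": masks,
        "matrix": matrix, "variants": variants, "truth": truth, "dir": out,
        "config": default_config,
    }
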