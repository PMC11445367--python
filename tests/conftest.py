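import pytest

import valleycross as vc


@pytest.fixture(scope="session")
def valley2():
    return vc.valley2_toy()


@pytest.fixture(scope="session")
def valley2_esc(valley2):
    return vc.esc_state(valley2, {"0"})


@pytest.fixture(scope="session")
def valley_y():
    return vc.valley_y_toy()


@pytest.fixture(scope="session")
def valley_y_esc(valley_y):
    return vc.esc_state(valley_y, {"0"})


@pytest.fixture(scope="session")
def examples():
    """All seven worked-example models, built once."""
    return {name: vc.make_example(name)
            for name in ("example1", "example2", "example3", "example4",
                         "example5", "example6", "example7")}


@pytest.fixture(scope="session")
def meta_graphs(examples):
    """Metastability graphs of the worked examples, built once."""
    return {name: vc.build_metastability_graph(model)
            for name, model in examples.items()}
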