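import pytest

from zahnreihen import load_fixture


@pytest.fixture(scope="session")
def v18638_quadrant():
    """The staged right maxilla of IVPP V18638 (the smallest Yinlong)."""
    (specimen,) = load_fixture("v18638_right_maxilla_stages")
    return specimen.quadrants[0]


@pytest.fixture(scope="session")
def yinlong_specimens():
    """The four-skull Yinlong ontogenetic series."""
    return load_fixture("yinlong_ontogeny")


@pytest.fixture(scope="session")
def ceratopsia_specimens():
    return load_fixture("ceratopsia_counts")
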