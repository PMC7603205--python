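import pytest
from hypothesis import settings

from rotoscreen.geometry import InstrumentConfig, make_dilution_layout

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def dilution_layout(r: int, n_rad: int):
    """Canonical dilution layout for an r-ring, n_rad-radius build."""
    return make_dilution_layout(
        InstrumentConfig(n_rings=r, n_radii=n_rad, combo_order=r, n_dilutions=r)
    )


@pytest.fixture
def layout_3x3():
    return dilution_layout(3, 3)


@pytest.fixture
def layout_2x2():
    return dilution_layout(2, 2)
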