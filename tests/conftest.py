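import numpy as np
import pytest

from chromacard.card_model import default_layout, default_palette
from chromacard.illumination_sim import RenderSpec, render_card


@pytest.fixture(scope="session")
def palette():
    return default_palette()


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def ideal_card(palette, layout):
    """Noise-free rendered card at the D50 reference colors."""
    return render_card(palette, layout, RenderSpec(width=180, height=300))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
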