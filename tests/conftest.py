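import numpy as np
import pytest

from octmargin.phantom import PhantomConfig, generate_margin


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A small but fully featured phantom: 8 B-scans, 2 lesions."""
    return PhantomConfig(
        n_bscans=8,
        bscan_height=420,
        bscan_width=564,
        n_lesions=2,
        lesion_span_bscans=(2, 4),
        lesion_width_px=(100, 160),
        lesion_height_px=(80, 140),
        seed=42,
        subject_id="S001",
        margin_id="M001",
    )


@pytest.fixture(scope="session")
def small_margin(small_config):
    return generate_margin(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
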