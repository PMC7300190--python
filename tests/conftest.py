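import numpy as np
import pytest

from mitomorph.core import BinaryMask
from mitomorph.synthetic import ImageSimConfig, ProteomeSimConfig, simulate_proteome_table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_image_cfg():
    """A fast, small field of view used across the image tests."""
    return ImageSimConfig(
        image_shape=(96, 96),
        n_slices=1,
        n_filaments=6,
        filament_length_um=(2.5, 0.8),
        fragment_fraction=0.2,
        seed=42,
    )


@pytest.fixture
def square_mask():
    m = np.zeros((14, 14), dtype=bool)
    m[2:12, 2:12] = True
    return BinaryMask(m, 0.1)


@pytest.fixture
def planted_proteome():
    cfg = ProteomeSimConfig(
        n_proteins=500,
        frac_changed=0.2,
        effect_size_log2=2.0,
        replicate_cv=0.1,
        n_replicates=3,
        missing_prob=0.05,
        frac_unique=0.05,
        n_isoform_groups=10,
        seed=99,
    )
    return cfg, simulate_proteome_table(cfg)
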