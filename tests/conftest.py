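import numpy as np
import pytest

from cadherlink.synthetic_data import FamilyConfig, generate_family


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def canonical_family():
    """Small all-canonical family with recorded ground truth."""
    cfg = FamilyConfig(
        repeat_count=3, species_count=4, substitution_rate=0.1,
        invariant_fraction=0.1, seed=11,
    )
    return generate_family(cfg)


@pytest.fixture(scope="session")
def mixed_family():
    """Family with one canonical and one noncanonical junction."""
    cfg = FamilyConfig(
        repeat_count=3, species_count=4,
        linker_classes=["canonical", "noncanonical"],
        substitution_rate=0.08, seed=5,
    )
    return generate_family(cfg)
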