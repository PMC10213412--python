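import numpy as np
import pandas as pd
import pytest

from soilfoodweb import GeneratorConfig, TraitReference, generate_dataset


@pytest.fixture(scope="session")
def default_traits():
    from soilfoodweb import load_default_traits

    return load_default_traits()


@pytest.fixture
def simple_traits():
    """Minimal hand-built trait table covering all guilds."""
    return TraitReference(
        pd.DataFrame(
            {
                "genus": ["BaOne", "BaTwo", "FuTwo", "OmFour", "PpThree"],
                "guild": ["Ba", "Ba", "Fu", "Om", "Pp"],
                "cp": [1, 2, 2, 4, 3],
                "body_mass": [0.5, 1.0, 0.4, 2.0, 0.8],
            }
        )
    )


@pytest.fixture(scope="session")
def dataset():
    return generate_dataset(seed=11)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(GeneratorConfig(seed=11).noise_free_copy())


def counts_frame(data: dict, samples=None) -> pd.DataFrame:
    """Build a count table from {genus: column} mapping."""
    df = pd.DataFrame(data, dtype=float)
    if samples is not None:
        df.index = samples
    df.index.name = "sample"
    return df
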