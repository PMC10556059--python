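import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("fixed", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def tissue_frame():
    """Default synthetic tissue table (seeded, session-shared, read-only use)."""
    from gulfweed import TissueGenConfig, gen_tissue_dataset

    return gen_tissue_dataset(TissueGenConfig(seed=11))


@pytest.fixture()
def quiescent_field():
    from gulfweed import FieldGenConfig, gen_field

    field, _ = gen_field(FieldGenConfig(kind="uniform", u0=0.0, v0=0.0))
    return field


@pytest.fixture()
def one_station():
    return pd.DataFrame(
        {"station_id": ["S1"], "longitude": [-60.0], "latitude": [20.0],
         "release_time": [0.0]}
    )
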