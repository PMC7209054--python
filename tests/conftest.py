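import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def occurrence_frame():
    """A small canonical occurrence frame covering two 100-km cells."""
    rows = []
    species = ["a", "a", "b", "c", "c", "c", "d", "e", "e", "f"]
    for i, sp in enumerate(species):
        rows.append(
            {
                "occurrence_id": str(i + 1),
                "collection_id": f"c{i // 2 + 1}",
                "taxon_name": sp,
                "taxon_rank": "species",
                "paleo_lon": 10.0 + (0.02 if i % 2 else 0.0),
                "paleo_lat": 45.0 + (3.0 if i >= 6 else 0.0),
                "max_ma": 72.0,
                "min_ma": 70.0,
                "reference_id": f"r{i // 4 + 1}",
                "region_code": "EU",
                "environment": "terrestrial",
                "group_tags": "",
                "bin_id": "bin_80_70",
            }
        )
    return pd.DataFrame(rows)
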