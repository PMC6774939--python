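import numpy as np
import pandas as pd
import pytest

from freqbias.ingest import FrequencyTable


@pytest.fixture
def tiny_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": [2000, 2000, 2001],
            "variant": ["A", "A", "B"],
            "agent": ["x", "y", "x"],
        }
    )


@pytest.fixture
def small_freq() -> FrequencyTable:
    # 3 years x 4 variants with ties and a late first appearance
    counts = [
        [5, 3, 1, 0],
        [4, 4, 0, 1],
        [1, 6, 2, 0],
    ]
    return FrequencyTable([2000, 2001, 2002], ["A", "B", "C", "D"], counts)


def make_freq(counts, years=None, variants=None) -> FrequencyTable:
    counts = np.asarray(counts)
    T, V = counts.shape
    if years is None:
        years = np.arange(2000, 2000 + T)
    if variants is None:
        variants = [chr(ord("A") + i) for i in range(V)]
    return FrequencyTable(years, variants, counts)
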