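import numpy as np
import pandas as pd
import pytest

from sludgeco.tables import OtuTable


def make_table(arr, taxa=None, samples=None, **kwargs) -> OtuTable:
    arr = np.asarray(arr)
    taxa = taxa or [f"OTU_{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=taxa, columns=samples)
    df.index.name = "#OTU ID"
    return OtuTable(df, **kwargs)


@pytest.fixture
def toy_table() -> OtuTable:
    return make_table([[5, 0, 2], [1, 1, 0], [0, 4, 4]])


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(42)
    return make_table(rng.integers(0, 50, size=(50, 6)))
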