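import numpy as np
import pandas as pd
import pytest

from chcscreen import default_panel
from chcscreen.matrix import ResponseMatrix


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture
def small_matrix():
    """3 receptors x 3 hydrocarbons with one missing cell."""
    mean = pd.DataFrame(
        [[87.5, 2.0, np.nan], [10.0, 20.0, 30.0], [-12.0, -11.0, -14.0]],
        index=["R1", "R2", "R3"],
        columns=["C27", "C28", "C29"],
        dtype=float,
    )
    return ResponseMatrix(mean=mean)
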