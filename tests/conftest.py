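import numpy as np
import pandas as pd
import pytest

from splicetox.screen_analysis import BarcodeLibrary


@pytest.fixture
def tiny_library() -> BarcodeLibrary:
    return BarcodeLibrary(
        pd.DataFrame(
            {
                "barcode": ["AAAA", "CCCC", "GGGG"],
                "shRNA_id": ["sh1", "sh2", "sh3"],
                "gene": ["G1", "G1", "G2"],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240117)
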