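import numpy as np
import pandas as pd
import pytest

from neutralline import BarcodeSpec, FeatureTable


@pytest.fixture
def specs():
    """Three samples with distinct 12-bp dual barcodes."""
    return [
        BarcodeSpec("S1", "ACGTACGTACGT", "TTGGCCAATTGG"),
        BarcodeSpec("S2", "GGTTAACCGGTT", "CAGTCAGTCAGT"),
        BarcodeSpec("S3", "TCTCTCTCAGAG", "GACGACGACGAC"),
    ]


@pytest.fixture
def small_table():
    """5 taxa x 6 samples, two sub-lines, hand-sized for exact checks."""
    counts = np.array(
        [
            [10, 20, 30, 5, 0, 8],
            [2, 0, 3, 0, 1, 0],
            [0, 0, 0, 0, 0, 0],  # all-zero taxon
            [5, 5, 5, 5, 5, 5],
            [1, 2, 0, 4, 9, 2],
        ]
    )
    sample_ids = [f"s{i}" for i in range(6)]
    meta = pd.DataFrame(
        {
            "sub_line": ["CF", "CF", "CF", "WIL1", "WIL1", "WIL1"],
            "generation": ["G1"] * 6,
            "day": ["D10"] * 6,
            "replicate": ["R1", "R2", "R3"] * 2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return FeatureTable(counts, [f"t{i}" for i in range(5)], sample_ids, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
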