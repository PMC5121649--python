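import numpy as np
import pytest

from tempomics.omics import MISSING, build_omics_object


@pytest.fixture
def tiny_object():
    """Three time-labelled samples, three components, one missing value."""
    return build_omics_object(
        [
            ("1", "GeneA", [1.0], ["chr1"]),
            ("1", "GeneB", [4.0], ["chr2"]),
            ("2", "GeneA", [2.0], ["chr1"]),
            ("2", "GeneB", [MISSING], ["chr2"]),
            ("2", "GeneC", [9.0], ["chr3"]),
            ("3", "GeneA", [3.0], ["chr1"]),
            ("3", "GeneB", [6.0], ["chr2"]),
        ]
    )


@pytest.fixture
def even_times():
    return np.arange(100, dtype=float)
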