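import numpy as np
import pytest

from reshwoa.filtering import ExpressionDataset
from reshwoa.synthetic_data import SyntheticSpec, generate


@pytest.fixture
def small_dataset():
    """25+25 samples, 300 genes, 10 planted at effect 3 — easily separable."""
    return generate(
        SyntheticSpec(n_class1=25, n_class2=25, n_genes=300, n_informative=10,
                      effect_size=3.0, seed=11)
    )


@pytest.fixture
def tiny_two_class():
    """Hand-built 4-sample, 3-gene dataset with known class statistics.

    Gene 0: class means 2 vs 1, both sample sds sqrt(1/2) -> SNR = 1/sqrt(2).
    Gene 1: equal means/sds in both classes -> SNR = 0, BC = 0.
    Gene 2: means differ by 2, sds 1 and 1 -> BC = 0.5.
    """
    half = np.sqrt(2) / 2
    matrix = np.array(
        [
            # class 1 (Tumour)
            [1.5, 5.0 - half, 3.0 - half],
            [2.5, 5.0 + half, 3.0 + half],
            # class 2 (Normal)
            [0.5, 5.0 - half, 1.0 - half],
            [1.5, 5.0 + half, 1.0 + half],
        ]
    )
    labels = np.array(["Tumour", "Tumour", "Normal", "Normal"])
    return ExpressionDataset(matrix, labels, ["g0", "g1", "g2"], ["s1", "s2", "s3", "s4"])
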