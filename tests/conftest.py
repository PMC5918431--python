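import numpy as np
import pytest

from mutembed.containers import MutationProfileSet


@pytest.fixture
def tiny_profiles() -> MutationProfileSet:
    return MutationProfileSet(
        [
            ("s1", {"TP53", "KRAS", "EGFR"}),
            ("s2", {"TP53", "KRAS", "BRAF"}),
            ("s3", {"EGFR", "BRAF", "PIK3CA"}),
        ]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
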