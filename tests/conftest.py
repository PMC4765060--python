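import numpy as np
import pandas as pd
import pytest

from bigih.core_io import CONTRA, IPSI, NAIVE, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 9 samples (3 per group) with known group means.

    UPGENE: ipsi 250 vs naive 100 (fc +2.5), contra 150 (fc +1.5);
    DOWNGENE: ipsi 50 vs naive 100 (fc -2), contra 25 (fc -4);
    FLATGENE: 100 everywhere (fc 1 both sides).
    """
    samples = [f"{g}_{i}" for g in ("ipsi", "contra", "naive")
               for i in (1, 2, 3)]
    groups = {s: {"ipsi": IPSI, "contra": CONTRA, "naive": NAIVE}[s.split("_")[0]]
              for s in samples}
    values = pd.DataFrame(
        [[250] * 3 + [150] * 3 + [100] * 3,
         [50] * 3 + [25] * 3 + [100] * 3,
         [100] * 9],
        index=pd.Index(["UPGENE", "DOWNGENE", "FLATGENE"], name="gene"),
        columns=samples, dtype=float)
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def all_present_calls(small_matrix) -> pd.DataFrame:
    rows = [(g, s, "present", 0.0)
            for g in small_matrix.genes for s in small_matrix.samples]
    return pd.DataFrame(rows, columns=["gene", "sample", "call", "p"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160224)
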