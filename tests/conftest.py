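import numpy as np
import pandas as pd
import pytest

from mebnet.bipartite import BipartiteNetwork
from mebnet.tables import OtuTable


@pytest.fixture
def small_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(6, 8))
    counts[0] = 0  # an OTU absent everywhere
    return OtuTable(
        [f"OTU{i}" for i in range(6)], [f"S{j}" for j in range(8)], counts, "bacteria"
    )


@pytest.fixture
def edge_list() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": ["E1", "E1", "E2", "E3"],
            "target": ["B1", "B2", "B1", "B3"],
            "rho": [0.8, -0.7, 0.65, -0.9],
            "p": [0.0, 0.01, 0.02, 0.0],
            "sign": ["positive", "negative", "positive", "negative"],
        }
    )


@pytest.fixture
def k22() -> BipartiteNetwork:
    return BipartiteNetwork.from_incidence(np.ones((2, 2)))


def brute_force_nodf(m: np.ndarray) -> float:
    """Independent NODF oracle: literal pair enumeration of the definition."""
    m = (np.asarray(m) > 0).astype(int)
    contribs = []
    for mat in (m, m.T):
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                fi, fj = mat[i].sum(), mat[j].sum()
                if fi == fj:
                    contribs.append(0.0)
                elif min(fi, fj) == 0:
                    contribs.append(0.0)
                else:
                    hi, lo = (mat[i], mat[j]) if fi > fj else (mat[j], mat[i])
                    shared = int(((hi > 0) & (lo > 0)).sum())
                    contribs.append(100.0 * shared / lo.sum())
    return float(np.mean(contribs))
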