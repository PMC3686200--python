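import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ecomcc import CommunityMatrix, DissimilarityMatrix


def make_community(abundances, sample_ids=None, taxa_ids=None, metadata=None):
    """Build a CommunityMatrix from a 2-D array with auto-generated metadata."""
    ab = np.asarray(abundances, dtype=float)
    n, t = ab.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    taxa_ids = taxa_ids or [f"tax{j + 1}" for j in range(t)]
    if metadata is None:
        metadata = pd.DataFrame(
            {
                "site": ["siteA"] * n,
                "plot": ["p1"] * n,
                "time": [str(2000 + i) for i in range(n)],
                "replicate": ["r1"] * n,
            },
            index=sample_ids,
        )
    return CommunityMatrix(pd.DataFrame(ab, index=sample_ids, columns=taxa_ids), metadata)


def euclidean_dm(coords, ids=None) -> DissimilarityMatrix:
    """DissimilarityMatrix of Euclidean distances between row coordinates."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] == 1:
        coords = coords.T
    n = coords.shape[0]
    ids = ids or [f"s{i + 1}" for i in range(n)]
    return DissimilarityMatrix(ids, squareform(pdist(coords)), kind="general")


def design_metadata(n_plots, n_times, n_reps, site="siteA"):
    """Metadata frame for a crossed plots x times design with replicates."""
    rows, ids = [], []
    for p in range(n_plots):
        for t in range(n_times):
            for r in range(n_reps):
                ids.append(f"{site}_p{p + 1}_t{t + 1}_r{r + 1}")
                rows.append(
                    dict(site=site, plot=f"p{p + 1}", time=str(2000 + t), replicate=f"r{r + 1}")
                )
    return pd.DataFrame(rows, index=ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_community():
    return make_community([[1, 0, 3], [0, 2, 1], [4, 4, 0], [2, 1, 1]])
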