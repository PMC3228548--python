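import numpy as np
import pytest

from gpbhc import TimeSeriesDataset, preprocess


def make_dataset(profiles, times=None, n_replicates=1, replicate_sd=0.0, seed=0):
    """Wrap a G x T profile matrix into a dataset (optionally replicated)."""
    profiles = np.asarray(profiles, dtype=float)
    G, T = profiles.shape
    times = np.arange(T, dtype=float) if times is None else np.asarray(times)
    rng = np.random.default_rng(seed)
    raw = profiles[None, :, :] + rng.normal(
        0.0, replicate_sd, size=(n_replicates, G, T)
    )
    return TimeSeriesDataset(
        gene_ids=[f"g{i}" for i in range(G)], times=times, raw=raw
    )


@pytest.fixture
def two_gene_dataset():
    ds = make_dataset([[0.0, 1.0, 2.0, 3.5], [3.0, 2.0, 1.0, -0.5]])
    preprocess(ds, use_replicate_prior=False)
    return ds
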