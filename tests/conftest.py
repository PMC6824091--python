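import numpy as np
import pandas as pd
import pytest

from morphovar import Configuration, Sample


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sample(rng, n=5, L=10, scale=0.3, prefix="sp"):
    """A generic valid sample: template plus modest noise, no structure."""
    template = rng.standard_normal((L, 3))
    configs = [
        Configuration(f"{prefix}{i + 1}", template + scale * rng.standard_normal((L, 3)))
        for i in range(n)
    ]
    return Sample(configs)


@pytest.fixture
def small_sample(rng):
    return random_sample(rng)


def synthetic_aligned(coords, ids=None):
    """Wrap raw (n, L, 3) coordinates as an AlignedSample-like object for
    operations that only need the aligned array (no GPA performed)."""
    from morphovar.superimposition import AlignedSample

    coords = np.asarray(coords, float)
    n, L, _ = coords.shape
    ids = ids or [f"s{i + 1}" for i in range(n)]
    mean = coords.mean(axis=0)
    return AlignedSample(
        aligned=coords,
        centroid_sizes=np.ones(n),
        consensus=Configuration("consensus", mean),
        iterations=0,
        converged=True,
        objective_history=np.zeros(1),
        specimen_ids=ids,
        landmark_ids=[str(i + 1) for i in range(L)],
        metadata=pd.DataFrame(index=ids),
        scaled=True,
    )
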