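from __future__ import annotations

import numpy as np
import pytest

from polarassess.assess import BuildConfig, build_reference
from polarassess.synthetic_data import default_spec, generate_reference


@pytest.fixture(scope="session")
def ref_spec():
    return default_spec(seed=11)


@pytest.fixture(scope="session")
def ref_dataset(ref_spec):
    return generate_reference(ref_spec)


@pytest.fixture(scope="session")
def ref_bundle(ref_dataset):
    ds = ref_dataset
    return build_reference(
        ds.embeddings, ds.annotations, ds.registry,
        expression=ds.expression, config=BuildConfig(seed=11),
    )


@pytest.fixture(scope="session")
def pow2_spec():
    # power-of-two arm size so centroid means (and hence the batch translation)
    # are exact on the generator's dyadic grid
    return default_spec(seed=13, n_per_arm=256)


@pytest.fixture(scope="session")
def pow2_dataset(pow2_spec):
    return generate_reference(pow2_spec)


@pytest.fixture(scope="session")
def pow2_bundle(pow2_dataset):
    ds = pow2_dataset
    return build_reference(
        ds.embeddings, ds.annotations, ds.registry,
        expression=ds.expression, config=BuildConfig(seed=13),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_blobs(seed=0, n=100, sep=6.0, d=3):
    """Two Gaussian blobs along axis 0; returns (features, labels)."""
    r = np.random.default_rng(seed)
    x0 = r.normal(0, 1, (n, d))
    x1 = r.normal(0, 1, (n, d))
    x1[:, 0] += sep
    X = np.vstack([x0, x1])
    y = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    return X, y
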