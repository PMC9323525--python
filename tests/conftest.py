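import numpy as np
import pytest

from ateem.parafac import fit_parafac
from ateem.preprocess import ScatterSpec, preprocess_dataset
from ateem.synthetic import default_config, simulate_dataset

# light fitter settings used throughout the suite: the synthetic
# 4-component problem is well conditioned, so a couple of starts and a
# moderate tolerance reach the same solution as the heavier defaults
FIT_KW = dict(n_starts=2, tol=1e-6, max_iter=600)


@pytest.fixture(scope="session")
def sim():
    """One default synthetic study (fixed seed), shared across tests."""
    return simulate_dataset(default_config(seed=1))


def _preprocess(sim, policy):
    labels = dict(zip(sim.sample_ids, sim.labels))
    return preprocess_dataset(
        sim.replicates, sim.absorbance, labels,
        ScatterSpec(fill_policy=policy), apply_ife=True,
    )


@pytest.fixture(scope="session")
def ds_masked(sim):
    """Preprocessed dataset with scatter cells masked (PARAFAC input)."""
    return _preprocess(sim, "mask")


@pytest.fixture(scope="session")
def ds_interp(sim):
    """Preprocessed dataset with scatter cells interpolated (PCA/PLS input)."""
    return _preprocess(sim, "interpolate_emission")


@pytest.fixture(scope="session")
def model4(ds_masked):
    """A 4-component non-negative PARAFAC fit of the shared dataset."""
    return fit_parafac(ds_masked, 4, seed=7, **FIT_KW)


@pytest.fixture(scope="session")
def rank1_array():
    """Exact rank-1 trilinear array built from known factors."""
    rng = np.random.default_rng(42)
    a = rng.uniform(1.0, 2.0, 12)
    b = rng.uniform(0.5, 1.5, 10)
    c = rng.uniform(0.5, 1.5, 8)
    return np.einsum("i,j,k->ijk", a, b, c), a, b, c
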