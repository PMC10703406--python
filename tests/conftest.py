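"""Shared fixtures: planted models, sampled alignments, and one expensive
session-scoped maximum-likelihood fit reused by the heavier tests."""

import numpy as np
import pytest

from generalist import FitConfig, fit
from generalist import synthetic
from generalist.msa import EncodedMSA


@pytest.fixture(scope="session")
def planted_k4():
    return synthetic.make_planted_model(length=30, k_true=4, seed=11)


@pytest.fixture(scope="session")
def planted_sample(planted_k4):
    """N=2000 alignment sampled from the planted K=4 model, with ground truth."""
    msa, z, labels = synthetic.sample_msa(planted_k4, 2000, seed=12)
    return {"msa": msa, "z": z, "labels": labels}


@pytest.fixture(scope="session")
def fitted_k4(planted_sample):
    """Model fitted at the true latent dimension on the planted sample."""
    return fit(planted_sample["msa"], FitConfig(k_dim=4, seed=3))


@pytest.fixture(scope="session")
def mixture_sample():
    """Two-population covarying alignment with planted cluster labels."""
    planted = synthetic.covarying_mixture_model(seed=21)
    msa, z, labels = synthetic.sample_msa(planted, 2000, seed=22)
    return {"planted": planted, "msa": msa, "z": z, "labels": labels}


@pytest.fixture(scope="session")
def edge_cases():
    return synthetic.edge_case_alignments(seed=0)


@pytest.fixture()
def small_random_msa():
    rng = np.random.default_rng(5)
    codes = rng.integers(0, 21, size=(20, 10)).astype(np.int8)
    return EncodedMSA(ids=[f"s{i}" for i in range(20)], codes=codes)


def column_shuffled(msa: EncodedMSA, seed: int = 33) -> EncodedMSA:
    """Independent per-column shuffle: preserves positional frequencies,
    destroys all cross-position covariation."""
    rng = np.random.default_rng(seed)
    codes = msa.codes.copy()
    for l in range(codes.shape[1]):
        codes[:, l] = rng.permutation(codes[:, l])
    return EncodedMSA(
        ids=[f"shuf_{i}" for i in range(codes.shape[0])],
        codes=codes,
        alphabet=msa.alphabet,
    )
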