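"""Ensemble distance distributions reported as survival curves.

Three diagnostics summarize where a generated ensemble sits in sequence
space relative to a natural alignment:

* ``random_pair``: fractional Hamming distances between random sequence
  pairs within one ensemble (the ensemble's overall expanse);
* ``nn_within``: each sequence's distance to its nearest neighbor in the
  same ensemble (local density);
* ``nn_to_natural``: each query sequence's distance to its nearest
  natural sequence (novelty versus memorization).

Each is reported as a survival curve S(h) = fraction of distances >= h on
the native grid h in {0, 1/L, ..., 1}, and two curves of the same kind
are compared by their Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .msa import EncodedMSA
from .selection import hmin_to_reference

#: Above this many pairs, random-pair distances are subsampled.
DEFAULT_MAX_PAIRS = 100_000


@dataclass
class DistanceProfile:
    kind: str  # random_pair | nn_within | nn_to_natural
    distances: np.ndarray
    grid: np.ndarray
    survival: np.ndarray

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_distances": int(self.distances.size),
            "mean_distance": float(self.distances.mean()),
            "grid": self.grid.tolist(),
            "survival": self.survival.tolist(),
        }


def _make_profile(kind: str, distances: np.ndarray, length: int) -> DistanceProfile:
    grid = np.arange(length + 1) / length
    # S(h) = fraction of distances >= h; exact on the native 1/L grid
    survival = (distances[None, :] >= grid[:, None] - 1e-12).mean(axis=1)
    return DistanceProfile(kind=kind, distances=distances, grid=grid, survival=survival)


def random_pair_distances(
    msa: EncodedMSA, n_pairs: int = DEFAULT_MAX_PAIRS, seed: int = 0
) -> DistanceProfile:
    """Distances between random distinct-sequence pairs within one ensemble.

    When the total number of unordered pairs is at most ``n_pairs`` the
    enumeration is exhaustive (exact distribution); otherwise ``n_pairs``
    pairs are sampled uniformly.
    """
    n = msa.n_sequences
    if n < 2:
        raise ValueError("need at least two sequences")
    total = n * (n - 1) // 2
    if total <= n_pairs:
        dists = pdist(msa.codes.astype(np.float64), metric="hamming")
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=n_pairs)
        j = rng.integers(0, n - 1, size=n_pairs)
        j = np.where(j >= i, j + 1, j)  # uniform over distinct pairs
        dists = (msa.codes[i] != msa.codes[j]).mean(axis=1)
    return _make_profile("random_pair", np.asarray(dists), msa.length)


def nn_within(msa: EncodedMSA) -> DistanceProfile:
    """Nearest-neighbor distance within an ensemble (self excluded)."""
    sample = hmin_to_reference(msa, msa, exclude_self=True)
    return _make_profile("nn_within", sample.values, msa.length)


def nn_to_natural(query: EncodedMSA, natural: EncodedMSA) -> DistanceProfile:
    """Each query sequence's distance to its closest natural sequence."""
    sample = hmin_to_reference(query, natural, exclude_self=False)
    return _make_profile("nn_to_natural", sample.values, query.length)


def profile_distance(a: DistanceProfile, b: DistanceProfile) -> float:
    """Kolmogorov-Smirnov statistic between two survival curves."""
    if a.kind != b.kind:
        raise ValueError(f"profile kinds differ: {a.kind} vs {b.kind}")
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("profiles are on different grids")
    return float(np.max(np.abs(a.survival - b.survival)))
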