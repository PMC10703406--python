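"""Gaussian-mixture clustering of latent embeddings and cluster contrasts.

The latent space groups sequences whose covariation statistics differ:
when the embedding cloud splits into sub-populations, the sequences in
each carry distinct frequency and covariance structure.  This module
fits full-covariance Gaussian mixtures to the embedding matrix, selects
the number of components by Jaccard stability of repeated fits, and
quantifies how different two clusters' sequence statistics are relative
to size-matched random partitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .msa import EncodedMSA
from .stats import sample_combinations, site_frequencies, _moment_values


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_components: int
    sizes: np.ndarray
    gmm_meta: dict

    def __post_init__(self) -> None:
        assert int(self.sizes.sum()) == self.labels.shape[0]


@dataclass
class StabilityReport:
    candidate_ns: list[int]
    jaccard_samples: dict[int, list[float]]
    chosen_n: int

    def to_dict(self) -> dict:
        return {
            "candidate_ns": self.candidate_ns,
            "jaccard_samples": {str(k): v for k, v in self.jaccard_samples.items()},
            "median_jaccard": {
                str(k): float(np.median(v)) for k, v in self.jaccard_samples.items()
            },
            "chosen_n": self.chosen_n,
        }


def fit_gmm(z: np.ndarray, n_components: int, seed: int = 0) -> ClusterAssignment:
    """Fit a full-covariance Gaussian mixture to latent embeddings.

    Labels are the maximum-posterior component per sequence.  Five EM
    restarts are run per call and the best likelihood kept; convergence is
    flagged in ``gmm_meta`` rather than raised.
    """
    z = np.asarray(z, dtype=np.float64)
    if z.shape[0] <= n_components:
        raise ValueError("need more points than mixture components")
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        n_init=5,
        max_iter=500,
        tol=1e-4,
        random_state=seed,
    )
    labels = gmm.fit_predict(z)
    sizes = np.bincount(labels, minlength=n_components)
    meta = {
        "seed": seed,
        "converged": bool(gmm.converged_),
        "log_likelihood": float(gmm.score(z) * z.shape[0]),
    }
    return ClusterAssignment(
        labels=labels, n_components=n_components, sizes=sizes, gmm_meta=meta
    )


def assignment_jaccard(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Pair-counting Jaccard similarity of two partitions.

    Over all unordered sequence pairs: pairs co-clustered in both
    partitions divided by pairs co-clustered in at least one.  Invariant
    under label permutation; equals 1 iff the partitions coincide.
    """
    la, lb = a.labels, b.labels
    if la.shape[0] != lb.shape[0]:
        raise ValueError("assignments cover different numbers of sequences")
    # contingency-table pair counting
    cont = np.zeros((a.n_components, b.n_components), dtype=np.int64)
    np.add.at(cont, (la, lb), 1)

    def _pairs(counts: np.ndarray) -> int:
        counts = counts.astype(np.int64)
        return int((counts * (counts - 1) // 2).sum())

    both = _pairs(cont.ravel())
    in_a = _pairs(cont.sum(axis=1))
    in_b = _pairs(cont.sum(axis=0))
    union = in_a + in_b - both
    if union == 0:  # both partitions are all singletons
        return 1.0
    return both / union


def select_n_components(
    z: np.ndarray,
    candidate_ns: list[int],
    n_iterations: int = 20,
    seed: int = 0,
) -> StabilityReport:
    """Choose the mixture size by Jaccard stability of repeated fits.

    Per candidate, ``n_iterations`` independent GMM pairs are fitted and
    their assignment Jaccard recorded; the candidate with the highest
    median wins (ties to the smaller candidate).  A single component is
    vacuously stable (every pair of fits agrees trivially), so candidates
    of 1 are reported but excluded from the selection whenever multi-
    component candidates exist.
    """
    if not candidate_ns:
        raise ValueError("candidate_ns must be nonempty")
    samples: dict[int, list[float]] = {}
    for n in candidate_ns:
        vals: list[float] = []
        for i in range(n_iterations):
            s = seed + 10_000 * n + 2 * i
            fa = fit_gmm(z, n, seed=s)
            fb = fit_gmm(z, n, seed=s + 1)
            vals.append(assignment_jaccard(fa, fb))
        samples[n] = vals
    eligible = [n for n in candidate_ns if n >= 2] or list(candidate_ns)
    chosen = min(
        sorted(eligible), key=lambda n: (-float(np.median(samples[n])), n)
    )
    return StabilityReport(
        candidate_ns=list(candidate_ns), jaccard_samples=samples, chosen_n=chosen
    )


def cluster_statistic_contrast(
    msa: EncodedMSA,
    assignment: ClusterAssignment,
    orders: tuple[int, ...] = (1, 2, 3, 4),
    n_samples: int = 1000,
    n_null: int = 100,
    seed: int = 0,
) -> dict[int, dict]:
    """Cross-cluster correlation of sequence statistics versus a null.

    Requires exactly two clusters (each of size >= 2).  Per order, the
    same sampled combinations are evaluated within each cluster and the
    two value vectors Pearson-correlated; the null repeats this for
    ``n_null`` random partitions with identical sizes.  Clusters with
    genuinely different covariation give observed correlations far below
    the null at orders >= 2.
    """
    if assignment.n_components != 2:
        raise ValueError("contrast is defined for exactly two clusters")
    if (assignment.sizes < 2).any():
        raise ValueError("both clusters must contain at least two sequences")
    rng = np.random.default_rng(seed)
    labels = assignment.labels
    rows0 = np.flatnonzero(labels == 0)
    rows1 = np.flatnonzero(labels == 1)

    def order_values(rows: np.ndarray, order: int, combos) -> np.ndarray:
        sub = msa.subset(rows)
        if order == 1:
            return site_frequencies(sub).ravel()
        positions, symbols = combos
        return _moment_values(sub, positions, symbols)

    out: dict[int, dict] = {}
    for order in orders:
        combos = (
            None
            if order == 1
            else sample_combinations(msa, order, n_samples, rng)
        )
        x0 = order_values(rows0, order, combos)
        x1 = order_values(rows1, order, combos)
        observed = float(np.corrcoef(x0, x1)[0, 1])
        null_rs = np.empty(n_null)
        for j in range(n_null):
            perm = rng.permutation(labels.shape[0])
            p0 = perm[: rows0.size]
            p1 = perm[rows0.size :]
            null_rs[j] = np.corrcoef(
                order_values(p0, order, combos), order_values(p1, order, combos)
            )[0, 1]
        out[order] = {
            "observed_r": observed,
            "null_mean": float(null_rs.mean()),
            "null_sd": float(null_rs.std(ddof=1)),
            "null_r": null_rs.tolist(),
        }
    return out
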