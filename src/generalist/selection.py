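"""Latent-dimension selection by matching nearest-neighbor distance means.

A generated ensemble should sit in sequence space the way the training
alignment does: each generated sequence as far from its closest natural
neighbor as natural sequences are from theirs.  The criterion is

    delta^2 = (<H_min>_generated - <H_min>_natural)^2,

where H_min is a sequence's fractional Hamming distance to its nearest
neighbor in the natural alignment (self-pairs excluded for the
natural-within-natural distribution).  Underfitted models (K too small)
produce generated sequences that are too far from the data
(<H_min>_generated > <H_min>_natural); overfitted ones (K too large)
nearly copy the data and the sign flips.  The optimal K minimizes
delta^2 averaged over restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .model import FitConfig, FitError, ModelState, fit, generate
from .msa import EncodedMSA

logger = logging.getLogger(__name__)

#: Cap on the generated-ensemble size used when scoring delta^2, bounding
#: the O(N^2 L) nearest-neighbor cost.
DEFAULT_MAX_GENERATED = 2000


@dataclass
class HminSample:
    """Nearest-neighbor fractional Hamming distances, one per query."""

    values: np.ndarray
    reference_set: str  # "natural" | "generated"

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ScanResult:
    """Full record of a latent-dimension scan."""

    k_grid: list[int]
    per_k_runs: dict[int, list[dict]]  # per K: [{seed, delta_sq, h_gen, h_nat}]
    delta_sq_mean: dict[int, float]
    k_optimal: int

    def to_dict(self) -> dict:
        return {
            "k_grid": self.k_grid,
            "per_k_runs": {str(k): v for k, v in self.per_k_runs.items()},
            "delta_sq_mean": {str(k): v for k, v in self.delta_sq_mean.items()},
            "k_optimal": self.k_optimal,
        }


def fractional_hamming(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Fraction of positions at which two equal-length sequences differ.

    The gap counts as an ordinary 21st symbol.
    """
    seq_a = np.asarray(seq_a)
    seq_b = np.asarray(seq_b)
    if seq_a.shape != seq_b.shape:
        raise ValueError("sequences must have equal length")
    return float(np.mean(seq_a != seq_b))


def hamming_matrix(queries: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """All-pairs fractional Hamming distances, ``Q x R``."""
    return cdist(
        np.asarray(queries, dtype=np.float64),
        np.asarray(reference, dtype=np.float64),
        metric="hamming",
    )


def hmin_to_reference(
    queries: EncodedMSA, reference: EncodedMSA, exclude_self: bool = False
) -> HminSample:
    """Per-query minimum fractional Hamming distance to a reference ensemble.

    With ``exclude_self`` the two ensembles must be the same object-level
    alignment (same shape) and each query skips its own row, giving the
    within-ensemble nearest-neighbor distribution.
    """
    if queries.length != reference.length:
        raise ValueError("query and reference alignments must share their length")
    if exclude_self:
        if queries.n_sequences != reference.n_sequences:
            raise ValueError("exclude_self requires queries == reference")
        if reference.n_sequences < 2:
            raise ValueError("no neighbor exists for a single-sequence ensemble")
    dist = hamming_matrix(queries.codes, reference.codes)
    if exclude_self:
        np.fill_diagonal(dist, np.inf)
    values = dist.min(axis=1)
    return HminSample(
        values=values, reference_set="within" if exclude_self else "reference"
    )


def delta_components(
    generated: EncodedMSA, natural: EncodedMSA
) -> tuple[float, float]:
    """``(<H_min>_generated, <H_min>_natural)`` for two ensembles."""
    h_gen = hmin_to_reference(generated, natural, exclude_self=False).mean
    h_nat = hmin_to_reference(natural, natural, exclude_self=True).mean
    return h_gen, h_nat


def delta_sq_from_ensembles(generated: EncodedMSA, natural: EncodedMSA) -> float:
    """The squared mean-H_min gap for an externally supplied ensemble."""
    h_gen, h_nat = delta_components(generated, natural)
    return (h_gen - h_nat) ** 2


def delta_sq(
    model: ModelState,
    natural: EncodedMSA,
    n_generated: int | None = None,
    seed: int = 0,
) -> float:
    """Generate an ensemble from ``model`` and score its mean-H_min gap."""
    if n_generated is None:
        n_generated = min(natural.n_sequences, DEFAULT_MAX_GENERATED)
    generated = generate(model, n_generated, seed=seed)
    return delta_sq_from_ensembles(generated, natural)


def scan_k(
    natural: EncodedMSA,
    k_grid: list[int],
    config: FitConfig,
    n_generated: int | None = None,
) -> ScanResult:
    """Scan latent dimensions, fitting ``n_restarts`` models per K.

    Restart ``i`` at latent dimension K uses seed
    ``config.seed + 1000 * K + i`` so every run is independently seeded
    and reproducible.  Failed fits are logged and excluded from the per-K
    mean; a K whose runs all fail is dropped from the optimum search.
    Ties in the mean resolve to the smallest K.
    """
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    per_k_runs: dict[int, list[dict]] = {}
    delta_sq_mean: dict[int, float] = {}
    for k in k_grid:
        runs: list[dict] = []
        for i in range(config.n_restarts):
            run_seed = config.seed + 1000 * k + i
            run_config = replace(config, k_dim=k, seed=run_seed)
            try:
                state = fit(natural, run_config)
            except FitError as exc:
                logger.warning("fit failed for K=%d seed=%d: %s", k, run_seed, exc)
                runs.append({"seed": run_seed, "failed": True})
                continue
            n_gen = n_generated or min(natural.n_sequences, DEFAULT_MAX_GENERATED)
            generated = generate(state, n_gen, seed=run_seed + 104729)
            h_gen, h_nat = delta_components(generated, natural)
            runs.append(
                {
                    "seed": run_seed,
                    "failed": False,
                    "delta_sq": (h_gen - h_nat) ** 2,
                    "h_min_generated": h_gen,
                    "h_min_natural": h_nat,
                }
            )
        per_k_runs[k] = runs
        ok = [r["delta_sq"] for r in runs if not r["failed"]]
        if ok:
            delta_sq_mean[k] = float(np.mean(ok))
    if not delta_sq_mean:
        raise FitError("every run failed at every latent dimension")
    k_optimal = min(sorted(delta_sq_mean), key=lambda k: delta_sq_mean[k])
    return ScanResult(
        k_grid=list(k_grid),
        per_k_runs=per_k_runs,
        delta_sq_mean=delta_sq_mean,
        k_optimal=k_optimal,
    )
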