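"""Summary-statistic comparison between two sequence ensembles.

Three layers of covariation statistics are exposed:

* positional amino-acid frequencies (order 1);
* central moments ("cumulants") of order 2-4 over mean-removed one-hot
  indicators at distinct positions, compared by Pearson correlation and
  best-fit slope;
* the r20 metric — for sampled sets of n positions, the Pearson
  correlation between the two ensembles' occurrence frequencies of the
  top-20 most frequent amino-acid strings at those positions, averaged
  over sets.  Restricting to the most frequent strings makes the metric
  robust to sampling noise at orders well beyond 4.

Within one comparison the same sampled position/symbol combinations are
evaluated in both ensembles, so model-to-model differences are paired and
free of combination-sampling variance.  The gap symbol participates
throughout as an ordinary 21st category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .msa import EncodedMSA

_MOMENT_CHUNK = 2048


class DegenerateStatisticError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


@dataclass
class MomentComparison:
    order: int
    natural_values: np.ndarray
    generated_values: np.ndarray
    pearson_r: float
    best_fit_slope: float

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "n_pairs": int(self.natural_values.size),
            "pearson_r": self.pearson_r,
            "best_fit_slope": self.best_fit_slope,
        }


@dataclass
class R20Curve:
    orders: list[int]
    mean_r: list[float]
    per_order_r: dict[int, list[float]]
    top_n: int
    n_combination_sets: int

    def to_dict(self) -> dict:
        return {
            "orders": self.orders,
            "mean_r": self.mean_r,
            "top_n": self.top_n,
            "n_combination_sets": self.n_combination_sets,
        }


def site_frequencies(msa: EncodedMSA) -> np.ndarray:
    """Per-position symbol frequencies as an ``A x L`` matrix (columns sum to 1)."""
    a = msa.alphabet.size
    n, length = msa.codes.shape
    freqs = np.zeros((a, length), dtype=np.float64)
    for l in range(length):
        freqs[:, l] = np.bincount(msa.codes[:, l], minlength=a)
    return freqs / n


def _moment_values(
    msa: EncodedMSA, positions: np.ndarray, symbols: np.ndarray
) -> np.ndarray:
    """Central moments for a batch of (position-set, symbol-set) combinations.

    ``positions``/``symbols`` have shape ``(n_combos, m)``; the result is
    ``E[prod_i (x_i - E[x_i])]`` over the ensemble's sequences, where
    ``x_i`` indicates symbol ``symbols[c, i]`` at ``positions[c, i]``.
    """
    codes = msa.codes
    n = codes.shape[0]
    out = np.empty(positions.shape[0], dtype=np.float64)
    for lo in range(0, positions.shape[0], _MOMENT_CHUNK):
        hi = min(lo + _MOMENT_CHUNK, positions.shape[0])
        # (chunk, m, N) indicators, centered within this ensemble
        ind = (codes.T[positions[lo:hi]] == symbols[lo:hi, :, None]).astype(np.float64)
        ind -= ind.mean(axis=2, keepdims=True)
        out[lo:hi] = ind.prod(axis=1).mean(axis=1)
    return out


def central_moment(
    msa: EncodedMSA, sites: list[tuple[int, int]], order: int | None = None
) -> float:
    """Central moment of one set of ``(position, symbol)`` indicator pairs.

    Positions must be distinct; with ``order`` given it must match the
    number of sites.
    """
    positions = np.array([[p for p, _ in sites]])
    symbols = np.array([[s for _, s in sites]])
    if order is not None and order != len(sites):
        raise ValueError(f"order {order} does not match {len(sites)} sites")
    if len(set(positions[0].tolist())) != positions.shape[1]:
        raise ValueError("positions within a moment must be distinct")
    return float(_moment_values(msa, positions, symbols)[0])


def sample_combinations(
    natural: EncodedMSA, order: int, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw random (position-set, symbol-set) combinations for moments.

    Positions are distinct uniform draws; each symbol is uniform among the
    symbols with nonzero frequency at its position in the natural
    alignment, avoiding a point mass of all-zero moments.
    """
    length = natural.length
    if length < order:
        raise ValueError(f"alignment length {length} < moment order {order}")
    freqs = site_frequencies(natural)
    observed = [np.flatnonzero(freqs[:, l] > 0) for l in range(length)]
    positions = np.empty((n_samples, order), dtype=np.intp)
    symbols = np.empty((n_samples, order), dtype=np.intp)
    for c in range(n_samples):
        pos = rng.choice(length, size=order, replace=False)
        positions[c] = pos
        for i, l in enumerate(pos):
            symbols[c, i] = rng.choice(observed[l])
    return positions, symbols


def _pearson_and_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticError(
            "correlation undefined: a value set is constant"
        )
    reg = sp_stats.linregress(x, y)
    return float(reg.rvalue), float(reg.slope)


def moment_comparison(
    natural: EncodedMSA,
    generated: EncodedMSA,
    order: int,
    n_samples: int = 50_000,
    seed: int = 0,
) -> MomentComparison:
    """Compare order-m statistics of two ensembles.

    Order 1 uses all ``A x L`` positional frequencies; orders 2-4 evaluate
    the same ``n_samples`` random combinations in both ensembles.  Reports
    the Pearson correlation and the least-squares slope of generated
    versus natural values (an accurate model gives r = slope = 1; slopes
    below 1 flag systematic under-prediction).
    """
    if natural.length != generated.length:
        raise ValueError("ensembles must share their alignment length")
    if order == 1:
        x = site_frequencies(natural).ravel()
        y = site_frequencies(generated).ravel()
    elif order in (2, 3, 4):
        rng = np.random.default_rng(seed)
        positions, symbols = sample_combinations(natural, order, n_samples, rng)
        x = _moment_values(natural, positions, symbols)
        y = _moment_values(generated, positions, symbols)
    else:
        raise ValueError("order must be in {1, 2, 3, 4}")
    r, slope = _pearson_and_slope(x, y)
    return MomentComparison(
        order=order,
        natural_values=x,
        generated_values=y,
        pearson_r=r,
        best_fit_slope=slope,
    )


def _pack_strings(codes: np.ndarray, positions: np.ndarray, a: int) -> np.ndarray:
    """Pack the symbols at ``positions`` of every sequence into one integer."""
    packed = np.zeros(codes.shape[0], dtype=np.int64)
    for l in positions:
        packed = packed * a + codes[:, l]
    return packed


def _top_string_frequencies(
    natural_codes: np.ndarray,
    generated_codes: np.ndarray,
    positions: np.ndarray,
    a: int,
    top_n: int,
) -> tuple[np.ndarray, np.ndarray] | None:
    nat = _pack_strings(natural_codes, positions, a)
    gen = _pack_strings(generated_codes, positions, a)
    values, counts = np.unique(nat, return_counts=True)
    if values.size < 2:
        return None
    # top_n by natural frequency, ties broken lexicographically by string
    order = np.lexsort((values, -counts))[:top_n]
    top_values = values[order]
    f_nat = counts[order] / nat.size
    f_gen = np.array(
        [np.count_nonzero(gen == v) for v in top_values], dtype=np.float64
    ) / gen.size
    return f_nat, f_gen


def r20(
    natural: EncodedMSA,
    generated: EncodedMSA,
    orders: list[int] | range = range(2, 11),
    top_n: int = 20,
    n_sets: int = 500,
    seed: int = 0,
) -> R20Curve:
    """Average top-string frequency correlation per covariation order.

    For each order n, draws ``n_sets`` random sets of n distinct
    positions; at each set the ``top_n`` most frequent amino-acid strings
    of the natural alignment are located and their occurrence frequencies
    in both ensembles are Pearson-correlated.  Position sets where the
    natural frequency vector is constant carry no signal and are skipped;
    a constant generated vector against a varying natural one scores 0
    (the ensemble captures none of the natural string variation).
    """
    if natural.length != generated.length:
        raise ValueError("ensembles must share their alignment length")
    a = natural.alphabet.size
    orders = list(orders)
    rng = np.random.default_rng(seed)
    mean_r: list[float] = []
    per_order_r: dict[int, list[float]] = {}
    for order in orders:
        if natural.length < order:
            raise ValueError(f"alignment length {natural.length} < order {order}")
        rs: list[float] = []
        for _ in range(n_sets):
            positions = rng.choice(natural.length, size=order, replace=False)
            pair = _top_string_frequencies(
                natural.codes, generated.codes, positions, a, top_n
            )
            if pair is None:
                continue
            f_nat, f_gen = pair
            if np.std(f_nat) == 0:
                continue
            if np.std(f_gen) == 0:
                rs.append(0.0)
                continue
            rs.append(float(np.corrcoef(f_nat, f_gen)[0, 1]))
        per_order_r[order] = rs
        mean_r.append(float(np.mean(rs)) if rs else float("nan"))
    return R20Curve(
        orders=orders,
        mean_r=mean_r,
        per_order_r=per_order_r,
        top_n=top_n,
        n_combination_sets=n_sets,
    )
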