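"""Core latent-space generative model for aligned sequence families.

Each sequence ``n`` carries a K-dimensional latent embedding ``z_n`` acting
as inverse-temperature-like coefficients on shared position- and
amino-acid-dependent energies ``theta_akl``.  Conditioned on its latent
point, a sequence's positions are independent categorical variables with
Gibbs-Boltzmann probabilities

    pi_anl = exp(-sum_k z_nk theta_akl) / Omega_nl,

where ``Omega_nl`` is an explicit 21-term sum over the symbols at one
position — no MCMC is ever needed.  Both ``theta`` and ``z`` are inferred
jointly by maximum likelihood with analytical gradients; generation
bootstraps the learned latent embeddings and samples positions
independently from the resulting categorical fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .alphabet import PROTEIN_ALPHABET, Alphabet
from .msa import EncodedMSA, one_hot

_MODEL_FORMAT_VERSION = 1


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting diverges."""


class ModelIOError(RuntimeError):
    """Raised when a model archive cannot be read back."""


@dataclass
class FitConfig:
    """Hyperparameters of the maximum-likelihood fit.

    ``step_size`` is the base step of the adaptive (Adam-style) full-batch
    ascent; ``tolerance`` is the relative log-likelihood improvement over a
    10-iteration window below which the fit stops.  ``n_restarts`` controls
    the multi-start protocol in :func:`fit_restarts` (restart ``i`` uses
    seed ``seed + i``).
    """

    k_dim: int
    max_iters: int = 2000
    step_size: float = 1e-2
    tolerance: float = 1e-6
    n_restarts: int = 10
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_dim < 1 or self.max_iters < 1 or self.n_restarts < 1:
            raise ValueError("k_dim, max_iters and n_restarts must be positive")
        if self.step_size <= 0 or self.init_scale <= 0 or self.tolerance < 0:
            raise ValueError("step_size/init_scale positive, tolerance nonnegative")


@dataclass
class ProbabilityField:
    """Per-sequence, per-position categorical distributions.

    ``pi`` has shape ``M x A x L`` and is normalized over the symbol axis;
    ``log_pi`` is the numerically exact log of ``pi`` (computed in log
    space, not by ``log(exp(...))`` round trips); ``log_omega`` holds the
    ``M x L`` log partition values.
    """

    pi: np.ndarray
    log_pi: np.ndarray
    log_omega: np.ndarray


@dataclass
class ModelState:
    """A fitted model: energies, latent embeddings and fit metadata."""

    theta: np.ndarray  # (A, K, L)
    z: np.ndarray  # (N, K)
    alphabet: Alphabet = field(default_factory=lambda: PROTEIN_ALPHABET)
    fit_meta: dict = field(default_factory=dict)

    @property
    def k_dim(self) -> int:
        return self.theta.shape[1]

    @property
    def length(self) -> int:
        return self.theta.shape[2]

    @property
    def n_sequences(self) -> int:
        return self.z.shape[0]


def _logits(theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Negative energies ``-(z . theta)`` with shape ``M x A x L``."""
    a, k, length = theta.shape
    flat = theta.transpose(1, 0, 2).reshape(k, a * length)
    return (-(z @ flat)).reshape(z.shape[0], a, length)


def probability_field(theta: np.ndarray, z: np.ndarray) -> ProbabilityField:
    """Evaluate the categorical probabilities for latent points ``z``.

    ``z`` may hold any number of rows (it need not be the training latent
    matrix).  The partition values are computed with max-subtracted
    log-sum-exp so arbitrarily large energies stay finite.
    """
    theta = np.asarray(theta, dtype=np.float64)
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if not (np.isfinite(theta).all() and np.isfinite(z).all()):
        raise FloatingPointError("theta and z must be finite")
    if theta.shape[1] != z.shape[1]:
        raise ValueError(
            f"latent dimension mismatch: theta K={theta.shape[1]}, z K={z.shape[1]}"
        )
    logits = _logits(theta, z)
    peak = logits.max(axis=1, keepdims=True)
    log_omega = peak[:, 0, :] + np.log(
        np.exp(logits - peak).sum(axis=1)
    )
    log_pi = logits - log_omega[:, None, :]
    return ProbabilityField(pi=np.exp(log_pi), log_pi=log_pi, log_omega=log_omega)


def log_likelihood(msa_onehot: np.ndarray, field: ProbabilityField) -> float:
    """Total data log-likelihood ``sum_nla sigma_anl log pi_anl`` (always <= 0)."""
    if msa_onehot.shape != field.log_pi.shape:
        raise ValueError(
            f"shape mismatch: one-hot {msa_onehot.shape} vs field {field.log_pi.shape}"
        )
    return float(np.sum(msa_onehot * field.log_pi))


def gradients(
    msa_onehot: np.ndarray, theta: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytical log-likelihood gradients with respect to theta and z.

    Returns the ascent direction: adding a small multiple of each gradient
    increases the log-likelihood.

        dL/dtheta_akl = sum_n z_nk (pi_anl - sigma_anl)
        dL/dz_nk      = sum_{l,a} theta_akl (pi_anl - sigma_anl)
    """
    field = probability_field(theta, z)
    diff = field.pi - msa_onehot  # (N, A, L)
    a, k, length = theta.shape
    n = z.shape[0]
    diff_flat = diff.transpose(0, 1, 2).reshape(n, a * length)
    theta_flat = theta.transpose(1, 0, 2).reshape(k, a * length)
    grad_theta = (diff_flat.T @ z).reshape(a, length, k).transpose(0, 2, 1)
    grad_z = diff_flat @ theta_flat.T
    if not (np.isfinite(grad_theta).all() and np.isfinite(grad_z).all()):
        raise FloatingPointError("non-finite gradient")
    return grad_theta, grad_z


def _ll_and_grads(
    onehot_flat: np.ndarray,
    codes: np.ndarray,
    theta: np.ndarray,
    z: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One fused evaluation of the likelihood and both gradients.

    Shares the logits/partition computation between the objective and the
    gradients, which dominates the per-iteration cost of `fit`.
    """
    a, k, length = theta.shape
    n = z.shape[0]
    theta_flat = theta.transpose(1, 0, 2).reshape(k, a * length)
    logits = (-(z @ theta_flat)).reshape(n, a, length)
    peak = logits.max(axis=1, keepdims=True)
    expl = np.exp(logits - peak)
    omega = expl.sum(axis=1)
    log_omega = peak[:, 0, :] + np.log(omega)
    picked = np.take_along_axis(logits, codes[:, None, :], axis=1)[:, 0, :]
    ll = float((picked - log_omega).sum())
    pi = expl / omega[:, None, :]
    diff = pi
    # subtract the one-hot indicators in place on the flat view
    diff_flat = diff.reshape(n, a * length)
    diff_flat -= onehot_flat
    grad_theta = (diff_flat.T @ z).reshape(a, length, k).transpose(0, 2, 1)
    grad_z = diff_flat @ theta_flat.T
    return ll, grad_theta, grad_z


def fit(msa: EncodedMSA, config: FitConfig) -> ModelState:
    """Jointly infer ``theta`` and ``z`` by full-batch gradient ascent.

    Parameters start uniform in ``(-init_scale, +init_scale)`` (near the
    uniform model).  The optimizer uses Adam-style per-parameter moment
    estimates with a backtracking acceptance rule: a step that lowers the
    log-likelihood is rejected and the global step scale halved, so the
    recorded trace of accepted log-likelihood values is non-decreasing.
    Deterministic given ``config.seed``.
    """
    if msa.n_sequences < 2:
        raise ValueError("fitting requires at least 2 sequences")
    a = msa.alphabet.size
    n, length = msa.codes.shape
    k = config.k_dim
    rng = np.random.default_rng(config.seed)
    theta = rng.uniform(-config.init_scale, config.init_scale, size=(a, k, length))
    z = rng.uniform(-config.init_scale, config.init_scale, size=(n, k))

    codes = msa.codes.astype(np.intp)
    onehot_flat = one_hot(msa).reshape(n, a * length)

    b1, b2, eps = 0.9, 0.999, 1e-8
    m_t = np.zeros_like(theta)
    v_t = np.zeros_like(theta)
    m_z = np.zeros_like(z)
    v_z = np.zeros_like(z)
    lr_scale = 1.0
    window = 10

    trace: list[float] = []
    best_ll = -np.inf
    best_params = (theta.copy(), z.copy())
    t = 0
    n_rejected = 0
    converged = False
    for it in range(config.max_iters):
        ll, g_t, g_z = _ll_and_grads(onehot_flat, codes, theta, z)
        if not np.isfinite(ll):
            raise FitError(f"log-likelihood diverged at iteration {it}")
        if ll < best_ll:
            # reject the step that produced these parameters
            theta, z = best_params[0].copy(), best_params[1].copy()
            lr_scale *= 0.5
            n_rejected += 1
            if lr_scale < 1e-12:
                break
            continue
        best_ll = ll
        best_params = (theta.copy(), z.copy())
        trace.append(ll)
        lr_scale = min(1.0, lr_scale * 1.1)
        if len(trace) > window:
            prev = trace[-window - 1]
            if abs(trace[-1] - prev) < config.tolerance * abs(prev):
                converged = True
                break
        t += 1
        step = config.step_size * lr_scale
        for g, m, v, p in ((g_t, m_t, v_t, theta), (g_z, m_z, v_z, z)):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p += step * mhat / (np.sqrt(vhat) + eps)

    theta, z = best_params
    meta = {
        "seed": config.seed,
        "k_dim": k,
        "n_iterations": len(trace),
        "n_rejected_steps": n_rejected,
        "final_log_likelihood": best_ll,
        "converged": converged,
        "trace": trace,
    }
    return ModelState(theta=theta, z=z, alphabet=msa.alphabet, fit_meta=meta)


def fit_restarts(
    msa: EncodedMSA, config: FitConfig, n_generated: int | None = None
) -> tuple[list[ModelState], ModelState]:
    """The multi-start protocol: fit ``n_restarts`` times, keep the best.

    Restart ``i`` uses seed ``config.seed + i``.  Each fitted model is
    scored by the squared mean nearest-neighbor gap of a generated
    ensemble (the same criterion used for latent-dimension selection) and
    the model with the smallest gap is returned as best; every state's
    ``fit_meta`` records its score under ``"delta_sq"``.
    """
    from .selection import delta_sq  # deferred: selection depends on this module

    states: list[ModelState] = []
    for i in range(config.n_restarts):
        run_config = replace(config, seed=config.seed + i)
        state = fit(msa, run_config)
        state.fit_meta["delta_sq"] = delta_sq(
            state, msa, n_generated=n_generated, seed=run_config.seed + 104729
        )
        states.append(state)
    best = min(states, key=lambda s: s.fit_meta["delta_sq"])
    return states, best


def embed(
    model: ModelState, msa: EncodedMSA, config: FitConfig | None = None
) -> np.ndarray:
    """Embed unseen sequences by optimizing ``z`` with ``theta`` frozen.

    An extension beyond the training pipeline: the same adaptive ascent
    is run on the latent coordinates only, giving each new sequence a
    position in the trained model's latent space.  Returns the ``M x K``
    embedding matrix.
    """
    if config is None:
        config = FitConfig(k_dim=model.k_dim, max_iters=500, seed=0)
    if config.k_dim != model.k_dim:
        raise ValueError("config.k_dim must match the trained model")
    a = model.alphabet.size
    m, length = msa.codes.shape
    if length != model.length:
        raise ValueError("sequence length does not match the trained model")
    rng = np.random.default_rng(config.seed)
    z = rng.uniform(-config.init_scale, config.init_scale, size=(m, model.k_dim))
    codes = msa.codes.astype(np.intp)
    onehot_flat = one_hot(msa).reshape(m, a * length)
    b1, b2, eps = 0.9, 0.999, 1e-8
    m_z = np.zeros_like(z)
    v_z = np.zeros_like(z)
    best_ll = -np.inf
    best_z = z.copy()
    for t in range(1, config.max_iters + 1):
        ll, _, g_z = _ll_and_grads(onehot_flat, codes, model.theta, z)
        if not np.isfinite(ll):
            raise FitError(f"embedding diverged at iteration {t}")
        if ll < best_ll:
            z = best_z.copy()
            continue
        best_ll, best_z = ll, z.copy()
        m_z = b1 * m_z + (1 - b1) * g_z
        v_z = b2 * v_z + (1 - b2) * g_z * g_z
        z = z + config.step_size * (m_z / (1 - b1**t)) / (
            np.sqrt(v_z / (1 - b2**t)) + eps
        )
    return best_z


def _sample_codes(pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample integer codes from an ``M x A x L`` categorical field."""
    m, a, length = pi.shape
    cdf = np.cumsum(pi, axis=1)
    # guard against cumulative rounding at the top of the cdf
    cdf[:, -1, :] = 1.0
    u = rng.random((m, 1, length))
    codes = (cdf < u).sum(axis=1)
    return np.minimum(codes, a - 1).astype(np.int8)


def generate(model: ModelState, n_out: int, seed: int) -> EncodedMSA:
    """Generate de novo sequences from a fitted model.

    Latent vectors are bootstrapped (drawn with replacement) from the
    learned embeddings; each position is then sampled independently from
    its categorical distribution.  Deterministic given ``seed``.
    """
    if n_out < 1:
        raise ValueError("n_out must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, model.n_sequences, size=n_out)
    field = probability_field(model.theta, model.z[idx])
    codes = _sample_codes(field.pi, rng)
    ids = [f"gen_{i}" for i in range(n_out)]
    return EncodedMSA(ids=ids, codes=codes, alphabet=model.alphabet)


def optimal_sequence(model: ModelState, z_point: np.ndarray) -> np.ndarray:
    """Closed-form most probable sequence at a latent point.

    Positions are conditionally independent given ``z``, so the global
    argmax is the per-position argmax of the categorical probabilities.
    Ties resolve to the lowest alphabet index (``argmax`` convention).
    """
    field = probability_field(model.theta, np.atleast_2d(z_point))
    return np.argmax(field.log_pi[0], axis=0).astype(np.int8)


def sequence_log_probability(
    model: ModelState, codes: np.ndarray, z_point: np.ndarray
) -> float:
    """Natural-log probability of one sequence at a latent point."""
    field = probability_field(model.theta, np.atleast_2d(z_point))
    length = field.log_pi.shape[2]
    return float(field.log_pi[0, np.asarray(codes, dtype=np.intp), np.arange(length)].sum())


def model_score(model: ModelState, z_point: np.ndarray) -> Callable[[np.ndarray], float]:
    """A black-box log-probability over sequences at a fixed latent point."""
    field = probability_field(model.theta, np.atleast_2d(z_point))
    log_pi = field.log_pi[0]
    pos = np.arange(log_pi.shape[1])

    def score(codes: np.ndarray) -> float:
        return float(log_pi[np.asarray(codes, dtype=np.intp), pos].sum())

    return score


def greedy_hill_climb(
    score: Callable[[np.ndarray], float],
    start: np.ndarray,
    max_sweeps: int = 100,
    seed: int = 0,
    n_symbols: int = 21,
) -> tuple[np.ndarray, list[float]]:
    """Greedy single-substitution ascent on a black-box sequence score.

    Proposes every (position, symbol) substitution in random order each
    sweep, accepting only strict improvements, and stops when a full sweep
    yields no acceptance (the sequence is then a local optimum under
    single substitutions) or ``max_sweeps`` is reached.
    """
    rng = np.random.default_rng(seed)
    current = np.asarray(start).copy()
    length = current.shape[0]
    best = score(current)
    if not np.isfinite(best):
        raise FloatingPointError("score is non-finite at the start sequence")
    trace = [best]
    proposals = [(l, a) for l in range(length) for a in range(n_symbols)]
    for _ in range(max_sweeps):
        accepted_any = False
        order = rng.permutation(len(proposals))
        for j in order:
            pos, sym = proposals[j]
            if current[pos] == sym:
                continue
            old = current[pos]
            current[pos] = sym
            val = score(current)
            if val > best:
                best = val
                trace.append(val)
                accepted_any = True
            else:
                current[pos] = old
        if not accepted_any:
            break
    return current, trace


def per_position_log_fold_improvement(
    score: Callable[[np.ndarray], float],
    start: np.ndarray,
    end: np.ndarray,
) -> float:
    """Per-position log10 probability fold change between two sequences.

    ``score`` returns natural-log probabilities; the result is
    ``(log10 P(end) - log10 P(start)) / L``.
    """
    start = np.asarray(start)
    end = np.asarray(end)
    if start.shape != end.shape:
        raise ValueError("sequences must have equal length")
    length = start.shape[0]
    return (score(end) - score(start)) / (length * np.log(10.0))


def save_model(model: ModelState, path) -> None:
    """Serialize a model to a portable ``.npz`` archive."""
    np.savez(
        path,
        format_version=np.array(_MODEL_FORMAT_VERSION),
        theta=model.theta,
        z=model.z,
        alphabet=np.array(model.alphabet.symbols),
        fit_meta=np.array(json.dumps(model.fit_meta, sort_keys=True)),
    )


def load_model(path) -> ModelState:
    """Load a model archive written by :func:`save_model`."""
    try:
        with np.load(path, allow_pickle=False) as data:
            version = int(data["format_version"])
            if version != _MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"unsupported model format version {version}, "
                    f"expected {_MODEL_FORMAT_VERSION}"
                )
            theta = data["theta"]
            z = data["z"]
            symbols = str(data["alphabet"])
            fit_meta = json.loads(str(data["fit_meta"]))
    except ModelIOError:
        raise
    except Exception as exc:  # corrupted archive, wrong keys, truncation
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    return ModelState(
        theta=theta, z=z, alphabet=Alphabet(symbols), fit_meta=fit_meta
    )
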