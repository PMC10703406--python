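# Methods

## Model

A multiple sequence alignment is treated as categorical data: N
sequences, L positions, A = 21 symbols (20 amino acids plus the gap,
which participates everywhere as an ordinary symbol). Each sequence n
has a latent embedding z_n ∈ R^K acting as inverse-temperature-like
coefficients on a shared energy tensor θ ∈ R^{A×K×L}:

    π_anl = exp(−Σ_k z_nk θ_akl) / Ω_nl ,   Ω_nl = Σ_a exp(−Σ_k z_nk θ_akl).

Conditioned on z_n, positions are independent; all epistasis lives in
the latent mixture. The partition value is an explicit 21-term sum, so
likelihoods, gradients and optima are all closed-form. The model is a
nonlinear tensor factorization in the spirit of restricted Boltzmann
machines, but with per-sequence visible-side coefficients instead of a
hidden-layer posterior.

The total log-likelihood is

    L(θ, Z) = Σ_{n,l,a} σ_anl log π_anl
            = −Σ_{n,l,a,k} σ_anl z_nk θ_akl − Σ_{n,l} log Ω_nl ,

with analytical gradients

    ∂L/∂θ_akl = Σ_n z_nk (π_anl − σ_anl),
    ∂L/∂z_nk  = Σ_{l,a} θ_akl (π_anl − σ_anl).

These are verified in the test suite against central finite differences
(worst relative error ~1e-7 on random instances).

### Identifiability

The likelihood is invariant under z → zG, θ → G⁻ᵀθ for any invertible
G acting on the latent axis, and under per-(l) symbol shifts of θ
absorbed by Ω. Raw parameters are therefore never compared between
fits; all comparisons go through probabilities or generated-ensemble
statistics.

## Estimation

Full-batch joint ascent on (θ, Z) with Adam-style per-parameter moment
estimates plus a backtracking acceptance rule: a proposed step that
lowers the log-likelihood is rejected and a global step scale is halved
(recovering multiplicatively on acceptance), so the recorded trace of
accepted log-likelihood values is non-decreasing by construction.
Defaults: step 1e-2, max 2000 iterations, stop when the relative
improvement over a 10-iteration window falls below 1e-6. Parameters
initialize uniform in (−0.1, 0.1) — near the uniform model. Partition
sums use max-subtracted log-sum-exp throughout, so |z·θ| of several
hundred stays finite; probabilities are produced by exponentiating log
probabilities, never the reverse.

Because the objective is non-convex with the indeterminacies above, the
multi-start protocol fits `n_restarts` models (restart i seeds with
base+i), scores each by Δ² (below) on a generated ensemble, and keeps
the smallest. Generated-statistic quality is empirically stable across
restarts (interquartile range of order-2 cumulant correlation < 0.05 on
planted data).

## Latent-dimension selection

For each generated sequence, H_min is its fractional Hamming distance
to the closest natural sequence; for each natural sequence, H_min is
the distance to its closest natural neighbor (self excluded; exact
duplicates keep their zero). The criterion

    Δ² = (⟨H_min⟩_generated − ⟨H_min⟩_natural)²

is minimized over a K grid, averaging over restarts; ties resolve to
the smaller K. Underfitting gives a positive gap, overfitting a
negative one; on the planted-K=4 study (N=2000, L=30) the gap moves
from +0.23 at K=1 to −0.29 at K=64 with the minimum at K=4. Distances
are computed exactly (vectorized integer comparison via scipy cdist;
no approximate nearest neighbors). The generated-ensemble size for Δ²
is capped at min(N, 2000) to bound the O(N²L) cost.

## Generation, optima and hill climbing

Generation bootstraps rows of the learned Z (sampling with
replacement), forms π, and samples positions independently;
deterministic given a seed; default ensemble size equals N so distance
comparisons are size-matched. The optimal sequence at a latent point is
the per-position argmax of π (exact, because positions are independent
given z), with ties resolved to the lowest alphabet index. A generic
greedy hill climb over single-position substitutions (random proposal
order, strict-improvement acceptance, termination on a sweep with no
acceptance) serves any black-box log-probability and is verified
against exhaustive neighborhood enumeration on small landscapes.
Improvement between two sequences is reported per position as
(log10 P(end) − log10 P(start))/L.

## Ensemble statistics

* **Site frequencies** — A × L empirical frequencies, no pseudocounts.
* **Central moments of order m ∈ {2,3,4}** — E[Π_i (x_i − E x_i)] over
  sequences, where x_i indicates a (position, symbol) pair; positions
  within a moment are distinct. Compared ensembles are evaluated on the
  same sampled combinations (50,000 by default; the symbol at each
  sampled position is drawn uniformly among symbols observed there in
  the natural alignment, avoiding a point mass of structural zeros),
  then summarized by Pearson r and the least-squares slope of generated
  versus natural values.
* **r20** — for each order n ∈ 2..10 and each of 500 sampled sets of n
  distinct positions, the 20 most frequent natural amino-acid strings
  at those positions (ties broken lexicographically) are located and
  their frequencies in the two ensembles Pearson-correlated; the curve
  reports the per-order mean. Sets where the natural top-string vector
  is constant carry no signal and are skipped; a constant *generated*
  vector against a varying natural one scores 0 — the ensemble captures
  none of the natural variation (this makes the uniform-random null
  score ≈ 0 instead of being undefined).

Column shuffling (independent per-column permutations) is the standard
null: it preserves order-1 statistics exactly and destroys all
covariation. Under it the order-2 cumulant correlation collapses to ≈ 0.
Note that r20 *at pair order* does not collapse under shuffling on
conserved families: the top pair strings owe most of their frequency to
marginal conservation, which shuffling preserves; the collapse appears
beyond pair order, and at all orders for the cumulant statistics.

## Distance diagnostics

Three survival curves S(h) = fraction of distances ≥ h on the native
grid h ∈ {0, 1/L, …, 1}: random-pair distances within an ensemble
(exhaustive below 100,000 pairs, sampled above), nearest neighbor
within an ensemble, and nearest natural neighbor. Curves of one kind
are compared by the Kolmogorov–Smirnov statistic. The nearest-neighbor
kernels are the same implementation used for Δ² and are cross-tested
against brute-force enumeration.

## Latent clustering

Full-covariance Gaussian mixtures (EM, 5 restarts per fit, 500
iterations, tol 1e-4) on the embedding matrix; labels are maximum
posterior. The number of components is chosen by stability: per
candidate, 20 independent pairs of fits are compared by the
pair-counting Jaccard index (co-clustered pairs in both / in at least
one — label-permutation invariant), and the highest median wins, ties
to the smaller candidate. A single component is vacuously stable (any
two trivial partitions agree perfectly), so candidate 1 is reported but
excluded from selection whenever multi-component candidates exist.

The two-cluster statistic contrast evaluates, per order, the same
sampled moment combinations within each cluster and correlates the two
value vectors; the null repeats this over 100 random partitions with
identical sizes. Clusters with genuinely different covariation fall far
below the null at orders ≥ 2 (observed r ≈ 0 versus null ≈ 0.98 on the
planted two-population study).

## Synthetic families

The planted generator draws θ i.i.d. uniform(−scale, scale) and latents
from a declared distribution, then samples sequences through the model's
own generative direction — so fits can be checked for statistic
recovery and clustering for label recovery against known ground truth.
Defaults: scale 4.0 with unit-mean ("consensus-centered") normal
latents. The unit mean gives marginally conserved positions — a family
centered on a wild-type — and the scale was set so the mean per-column
entropy (~2.7 bits, dominant residue ~40%) matches typical
protein-family conservation; a zero-mean latent option produces
maximally entropic, covariation-only families and is used where pure
covariation structure is wanted. A two-population mixture preset
(components at ±2 per latent axis, within-population s.d. 0.5, i.e.
component centers 4 within-population standard deviations apart per
axis) plants strong cluster structure for the clustering and r20
robustness studies. Fixture sizes are capped (N ≤ 2000, L ≤ 50) so the
full suite runs in minutes on one CPU; the heavier studies use N=2000,
L=30, K_true=4, and the K scan {1, 2, 4, 16, 64} with one restart per
K.

These alignments carry no phylogeny, no insertion structure, no
position-dependent gap patterns and no functional constraints; passing
tests demonstrate correctness and calibration of the machinery on data
the model family can represent, not fidelity to any real protein
family.

## Numerical and policy choices

* Alphabet fixed as `ACDEFGHIKLMNPQRSTVWY-`; ambiguous residue codes
  (B, Z, X, J, U, O, `.`) map to the gap with a logged count; lowercase
  is uppercased; only fixed-width aligned FASTA is supported.
* All argmax tie-breaks resolve to the lowest index; hill-climb
  acceptance is strictly-greater.
* Every CLI run derives all randomness from one `--seed`; JSON outputs
  are sorted-key and byte-identical across reruns. Run manifests record
  the resolved parameters and package version but deliberately no wall
  time, preserving byte-level reproducibility.
* Model archives are numpy `.npz` (endianness-safe) with a format
  version and JSON metadata blocks.

## Limitations

No phylogenetic reweighting (deliberate: all sequence weights are one),
no regularization or priors on θ or z, no mini-batch or GPU path, and
no support for Stockholm/A2M dialects. Statistic-recovery margins
depend on alignment entropy: on maximally entropic synthetic families
the planted signal in order-1 frequencies approaches the multinomial
sampling floor at N=2000, and no inference method can correlate above
what two independent samples of the truth achieve. The `embed`
operation (frozen-θ latent fit for unseen sequences) is an extension
beyond the training pipeline and is validated only on held-out
synthetic populations.
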