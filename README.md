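# generalist

Latent-space generative modeling of aligned protein sequence families —
an implementation of the GENERALIST model (generative nonlinear
tensor factorization) with training, latent-dimension selection, de novo
sequence generation, local-optimum search, higher-order covariation
diagnostics, distance-distribution diagnostics, and latent-space
clustering. It is aimed at protein scientists and engineers who want a
simple, tunable generative description of a multiple sequence alignment
(MSA), including for large proteins with small alignments where
Potts-type and deep models struggle.

## The model

Given an MSA of N sequences of length L over A = 21 symbols (20 amino
acids + gap), each sequence n carries a K-dimensional latent embedding
z_n, and positions are conditionally independent categorical variables:

    π_anl = exp(−Σ_k z_nk θ_akl) / Ω_nl,
    Ω_nl = Σ_a exp(−Σ_k z_nk θ_akl),

where θ is a shared A × K × L energy tensor and Ω_nl is an explicit
21-term partition sum — no MCMC anywhere. Both θ and z are inferred by
maximum likelihood,

    L = Σ_nla σ_anl log π_anl,

with analytical gradients (σ is the one-hot encoding of the alignment).
The latent dimension K is selected by matching nearest-neighbor
distance means: Δ² = (⟨H_min⟩_generated − ⟨H_min⟩_natural)², where
H_min is a sequence's fractional Hamming distance to its closest
natural neighbor. Small K underfits (generated sequences too far from
the data, positive gap); large K overfits (near-copies, negative gap);
the selected K minimizes Δ² averaged over restarts.

New sequences are generated by bootstrapping the learned embeddings and
sampling each position from its categorical distribution. Because
positions are independent given z, the most probable sequence at any
latent point is the per-position argmax, in closed form.

## Worked example

Everything below is driven by synthetic planted-parameter families, so
it runs anywhere with no downloads:

```
generalist make-fixture --preset planted-k4 --n 400 --seed 11 --out fx
generalist fit --msa fx/alignment.fasta --k 4 --max-iters 800 --seed 7 --out model.npz
generalist generate --model model.npz --n 400 --seed 1 --out generated.fasta
generalist stats --natural fx/alignment.fasta --generated generated.fasta \
    --orders 1-4 --r20-orders 2-6 --n-samples 10000 --n-sets 200 --seed 3 \
    --out report.json
```

The fit reports `fitted K=4 on N=400 L=30: log-likelihood -6809.82`,
and `report.json` contains (reformatted):

```
order 1: pearson_r=0.997 slope=1.024
order 2: pearson_r=0.954 slope=0.987
order 3: pearson_r=0.733 slope=0.818
order 4: pearson_r=0.485 slope=0.468
r20 orders:  [2, 3, 4, 5, 6]
r20 mean_r:  [0.981, 0.946, 0.904, 0.862, 0.784]
```

Order-m rows compare central moments ("cumulants") of the generated
versus natural ensemble over the same sampled position/symbol
combinations — r and slope near 1 mean the model reproduces the
statistic without systematic under-prediction. At this small N the raw
order-3/4 moment clouds are noise-limited; the r20 rows, which track
only the top-20 most frequent amino-acid strings per sampled position
set and are therefore robust to sampling noise, show the covariation is
captured well beyond pair order. Selecting K on the same fixture,

```
generalist scan-k --msa fx/alignment.fasta --k-grid 1,2,4,8,16 \
    --restarts 2 --max-iters 800 --seed 5 --out scan.json
```

prints `optimal latent dimension: K=4` with per-K mean Δ² of
`{1: 0.0281, 2: 0.0119, 4: 0.00358, 8: 0.0206, 16: 0.0788}` — the
planted dimension is recovered as the Δ² minimum.

Other subcommands: `optimize` (closed-form optimal sequence at every
training embedding), `distances` (random-pair / nearest-neighbor /
nearest-natural survival curves with KS summaries), `cluster`
(latent-space Gaussian-mixture clustering with Jaccard-stability
selection of the component count).

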