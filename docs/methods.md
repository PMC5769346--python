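# Methods

This note documents the statistical model, the algorithms and the numerical
choices behind `crossdomnet`, and what the synthetic validation does and does
not establish.

## Model

Let `W ∈ ℕ^{n×d}` and `V ∈ ℕ^{n×p}` be the (unobservable) absolute
abundances of bacterial and fungal taxa in `n` samples. The model assumes the
log basis is jointly Gaussian, `log(W, V) ~ N(μ, Σ)`, with a sparse precision
matrix `Ω = Σ^{-1}` whose off-diagonal support is the association graph:
`Ω_ij = 0` means taxa i and j are conditionally independent given all others.
Sequencing observes only compositions `x = w/M`, `y = v/N` at arbitrary
per-sample, per-domain library sizes `M, N`.

The centered log-ratio transform is invariant to the library size, and the
covariance of `clr(X)` equals `G_d Σ_W G_d` with `G_d = I - (1/d)·11'` the
centering matrix. For `d` large, `G_d ≈ I`, so the CLR covariance is a usable
plug-in for the log-basis covariance. The same identity holds blockwise for
the concatenation `Z = [clr(X) clr(Y)]`: its population covariance is the
centered version of the full `(d+p)×(d+p)` log-basis covariance, including
the cross-domain block. Crucially, each domain is centered *by its own
geometric mean*; closing the concatenated counts as a single composition
would instead couple every taxon to the technical `M/N` ratio (the two
markers do not compete for reads), which is the failure mode quantified in
`examples/03_naive_concatenation_pitfall.py`.

The estimator is the off-diagonal-penalized Gaussian MLE (graphical lasso)

    Ω̂ = argmin_{Ω≻0} -log det Ω + tr(Ω S) + λ Σ_{i≠j} |Ω_ij| ,

where `S` is by default the *correlation* rescaling of the sample covariance
of `Z`. Working on the correlation scale makes the uniform penalty
scale-equivariant across taxa with very different CLR variances (a direct
consequence of heterogeneous depths and abundances) and matches the behavior
of the standard implementation stack for this estimator; edge weights are
unaffected, because partial correlations are invariant to diagonal
rescaling. `use_correlation=False` restores the raw-covariance objective.

## Algorithms

**Glasso solver.** ADMM on the splitting `Θ = Z`: the smooth subproblem has
a closed form via one eigendecomposition per iteration, the penalty
subproblem is an off-diagonal soft-threshold (hence the support is exactly
sparse), and residual balancing adapts the ADMM penalty. Convergence is
declared on the duality gap (dual point: the primal inverse projected onto
the box `|W − S| ≤ λ`, with `W_ii = S_ii` for the unpenalized diagonal);
default gap tolerance 1e-4·dim, 1e-3 for subsample fits, 1e-9 in optimality
tests. An ADMM splitting was chosen over primal coordinate descent because
it is simpler to verify (tests check the KKT conditions directly to 1e-5 and
match an independent proximal-gradient oracle and sklearn's implementation)
and warm-starts cleanly along the penalty path. The diagonal is unpenalized
by default (keeps the estimator full rank); `penalize_diagonal=True` is
available.

**Penalty path.** 20 log-spaced values from `λ_max` (the largest
off-diagonal |S|, the smallest penalty giving an empty graph) down to
`λ_max/100`, warm-started sparse→dense.

**StARS.** For each of 50 subsamples (without replacement, size
`min(⌊10√n⌋, 0.8n, n−1)` — the 0.8n cap keeps subsamples distinct on small
cohorts, where `⌊10√n⌋ ≈ n` would make every model look stable) the full
path is refit; per-edge selection frequencies `θ̂` give the per-λ instability
`mean 2θ̂(1−θ̂)` over node pairs, monotonized by a running maximum from the
sparse end. The selected model is the densest one whose monotonized
instability is at or below `β = 0.1`, refit on the full data; edge presence
is decided by that refit's support, not by frequency thresholding. If no
penalty meets the threshold the sparsest model is returned with
`converged=False` and a warning. All subsampling is seeded; identical
config ⇒ identical network, byte-for-byte through the pipeline writer.

**Preprocessing defaults.** Sample read floors 1000 (16S) and 50 (ITS);
OTU prevalence threshold `ceil(n/3)` nonzero samples (computed per input
table, before cross-domain sample intersection, since per-domain sample sets
differ); OTUs with count ≤ 1 wherever present are removed as sequencing
noise; pseudocount 1 added before total-sum scaling; natural logarithm
throughout (the base cancels in the estimator but must be consistent).
Cross-domain assembly intersects exact sample-id strings (an id map handles
run-specific naming) and namespaces OTU ids by domain.

## Topology battery

All topological metrics run on the unweighted, sign-agnostic graph; the
signed weights enter only PEP and the reporting tables. Choices that were
genuinely open:

- **Modularity maximization** is Newman's deterministic leading-eigenvector
  spectral bisection with Kernighan–Lin-style single-vertex fine-tuning,
  recursing with the generalized modularity matrix until no split increases
  Q; the module count emerges from the recursion. It is deterministic (ties
  break by node index); the `seed` parameter exists for interface uniformity
  only. Analysis runs on the largest connected component. *Realized
  modularity* is reported as the fraction of edges falling within modules
  (∈ [0,1]; 1 iff no inter-module edge).
- **Expected commute time** uses the Laplacian spectrum:
  `Σ_{i<j} R_eff(i,j) = n Σ_k 1/μ_k` over nonzero eigenvalues, commute
  `= 2m·R_eff`. The report defaults to the *mean over unordered pairs* and
  also offers the raw *sum*; the normalization used is always recorded,
  since published totals do not disambiguate the constant.
- **Estrada classification** uses the odd-walk subgraph centrality
  `SC_odd(i) = Σ_j v_ji² sinh(λ_j)` (computed via `exp(λ_j − λ_1)` scaling
  for numerical range) against the spectral-scaling law
  `sinh(λ_1) v_1i²`. Modular structure adds further large positive
  adjacency eigenvalues, pushing nodes above the law; tree-like peripheries
  add large negative eigenvalues, pulling them below. Hence: deviation
  spread ≤ 0.01 (log10) → class I; positive departures only → II (modular);
  negative only → III (core-periphery); both → IV. The spread rule makes
  vertex-transitive graphs class I exactly: their uniform offset is the
  finite-size correction from subdominant eigenvalues, not heterogeneity.
  Bipartite graphs have `SC_odd ≡ 0` and are reported as unclassifiable.
- **Attack robustness** recomputes the removal criterion after every removal
  (adaptive attack; a static-order mode sits behind `recompute=False`),
  ties break toward the lexicographically smallest node; random removal
  averages 100 seeded orderings. Curves are LCC size relative to the
  starting LCC, which is non-increasing; AUC is by trapezoid over the
  removed fraction.
- **Enrichment** of flagged OTUs per module is a hypergeometric upper tail
  with Benjamini–Hochberg adjustment across modules (the analysis only
  claims "enrichment", so the simplest exact test is used and named).
- **Status-exclusive OTUs** use strictly-zero pre-pseudocount counts outside
  the group; the reported subnetwork is the closed neighborhood (exclusive
  OTUs plus their direct neighbors).
- **Welch comparisons** of degree and pairwise-distance distributions use
  summary statistics (Satterthwaite df). Pairwise distances between nodes
  are not independent observations, so these p-values are descriptive, as
  is conventional for network comparison.

## Synthetic generator

`make_precision` draws a within-domain support per block (band of width 2;
clusters = groups of ~10 taxa wired with probability 0.3; preferential
attachment; hub stars) plus a requested number of uniformly placed
cross-domain edges; entries get magnitude U(0.25, 0.45) with random sign,
and a common diagonal loading sets the condition number to 10. That target
keeps the truth well-conditioned with partial correlations ≈ 0.17–0.30 —
detectable but not trivial at n = 200 (≈ `sqrt(log p / n)` ≈ 0.14 is the
detectability scale). Near-singular truths (condition numbers in the
hundreds) concentrate the covariance in one near-null mode and make
recovery fail for every estimator; they test conditioning, not inference.

`sample_counts` draws latent log abundances `N(0, Ω^{-1})`, exponentiates,
closes each domain separately and draws per-domain multinomial reads at
per-sample depths log-uniform on [1e3, 1e5] (16S) and [1e2, 1e4] (ITS),
mimicking typical unequal paired library sizes.

What the generator emulates: compositionality, unequal and random library
sizes, domain-wise closure, count noise and the induced zeros at shallow
depth. What it does not: taxon-specific zero inflation beyond multinomial
sampling, overdispersion beyond log-normality, real abundance profiles,
sample relatedness (repeated hosts), or taxonomic signal in the wiring
(phylum labels are assigned round-robin). Passing recovery tests therefore
show the estimator works under the stated generative model at the stated
signal strength — not that real lung or skin networks are recovered at any
particular fidelity.

## Validation operating points

Tests and the acceptance script use: the reference recovery experiment at
d=30, p=20, 15 cross edges, n=200, 50 StARS subsamples, β=0.1 (F1 ≈ 0.7,
cross-block F1 ≈ 0.7); sample-size consistency and the naive-concatenation
contrast over 10 replicate truths at n ∈ {50, 200, 1000} and n=200
respectively, both scored by the best F1 along the penalty path (oracle λ),
which isolates the representation question from selection noise; solver
optimality on 50 random 4–6-variable instances × 3 penalties against a
proximal-gradient oracle (objective and KKT residuals ≤ 1e-5); topology
metrics against exhaustive enumeration on 200 random ≤ 8-node graphs; and
commute time against seeded random-walk simulation (within 2%). These sizes
were chosen so the full suite runs in well under ten minutes on one CPU.

## Known limitations

- The CLR ≈ log-basis approximation degrades for small taxon counts per
  domain (error ~1/d per entry); with d, p in the tens it contributes a
  visible floor to recovery accuracy (the n=1000 plateau in the consistency
  test).
- StARS at β=0.1 tends to select slightly denser models than the F1-optimal
  penalty; precision/recall trade-off is visible in the acceptance output.
- Only the glasso variant is implemented (no neighborhood-selection mode,
  no edge confidence intervals).
- Estrada classification is undefined on bipartite components; the battery
  reports it as absent rather than guessing.
- Pairwise-distance Welch tests treat dependent pairs as a sample;
  interpret them as effect-size descriptions, not calibrated inference.
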