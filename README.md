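# crossdomnet

Cross-domain microbial association networks from targeted-amplicon count
tables — and the topology battery to compare them.

## The problem

Bacterial (16S rRNA) and fungal (ITS) communities in the same habitat are
usually surveyed with separate marker-gene sequencing runs, and association
networks are then inferred for each domain alone. That misses every
bacterial–fungal interaction and, as it turns out, distorts the global
topology of the network you do infer. Joining the two count tables is not
straightforward, though: each sequencing run yields *compositional* data
(only relative abundances are meaningful, with a per-sample library size that
is a technical artifact), and because the two markers are amplified
separately, the two domains never competed for reads — so the ratio of
bacterial to fungal counts in a sample carries no biological signal at all.

`crossdomnet` implements the compositionally robust route. For each domain,
counts are pseudocounted, closed to relative abundances (total-sum scaling)
and mapped through the centered log-ratio transform,

```
clr(x)_i = log( x_i / g(x) ),        g(x) = (prod_i x_i)^(1/d),
```

which is invariant to each sample's library size. The per-domain CLR matrices
are concatenated column-wise,

```
Z = [ clr(X)  clr(Y) ],
```

and the covariance of `Z` approximates the covariance of the latent log
absolute abundances (exactly so as the number of taxa per domain grows). A
sparse precision matrix is then estimated by the graphical lasso,

```
Ω̂ = argmin_{Ω ≻ 0}  -log det Ω + tr(Ω Γ̂_Z) + λ ||Ω||_1,off ,
```

with the penalty λ chosen by StARS (Stability Approach to Regularization
Selection): the densest model whose edge set stays stable across random
subsamples of the data (instability ≤ 0.1). Non-zero off-diagonal entries of
`Ω̂` are conditional-dependence edges; their weights are the partial
correlations `ρ_ij = -Ω̂_ij / sqrt(Ω̂_ii Ω̂_jj)`, signed associations between
taxa within and across domains. The same construction extends to three or
more domains.

On top of the inferred network, the package provides the comparison battery
used to contrast single-domain and cross-domain networks: component census,
degree and shortest-path statistics, normalized betweenness, phylum
assortativity, deterministic modularity maximization with realized
modularity, expected commute time, spectral-scaling (Estrada) topological
classification, attack-robustness curves, positive edge percentage (PEP),
keystone-candidate tables, status-exclusive subnetworks with hypergeometric
module enrichment, and Welch-test network comparison.

Because real paired surveys come without ground truth, the package includes a
generator of paired-domain synthetic experiments: a sparse joint precision
matrix with designated within- and cross-domain edges, log-normal latent
abundances, and per-domain multinomial read sampling at unequal depths.

**Audience:** microbial ecologists and bioinformaticians with paired
amplicon surveys (16S + ITS or more) who want within- and cross-domain
association networks, and methodologists benchmarking compositional network
inference.

## Worked example

```bash
python examples/01_infer_cross_domain_network.py
```

```
selected lambda        : 0.1907 (instability threshold beta=0.1, 50 subsamples)
edges inferred / true  : 90 / 83
cross-domain edges     : 22 (24.44% of all edges)
edge recovery          : F1=0.740 (precision 0.711, recall 0.771)
cross-block recovery F1: 0.757
```

A known 50-taxon truth (30 bacterial, 20 fungal, 83 edges of which 15 cross
domains) generated 200 paired samples; StARS picked λ = 0.19, the inferred
network has 90 edges, and 74% of the edge decisions match the generating
graph — the finite-sample operating point of the graphical lasso at this
signal strength. The cross-block F1 of 0.76 says bacterial–fungal edges are
recovered about as reliably as within-domain ones, which is the point of the
per-domain CLR construction: `examples/03_naive_concatenation_pitfall.py`
shows that treating the concatenated counts as one composition instead
drops cross-block recovery to roughly half, in 10/10 replicates.

Other entry points:

- `examples/02_topology_battery.py` — the full topology report and a
  cross-domain vs bacterial-only comparison.
- CLI: `crossdom-net simulate|preprocess|infer|topology|compare`, e.g.

  ```bash
  crossdom-net simulate --d 30 --p 20 --n 200 --seed 7 --out sim/
  crossdom-net infer --counts16s sim/counts_16S.tsv --countsits sim/counts_ITS.tsv \
      --beta 0.1 --seed 7 --out network.graphml
  crossdom-net topology --graph network.graphml --out report.json
  ```

Real data enters as tab-separated OTU tables (either orientation,
auto-detected) or BIOM (1.0 JSON / 2.1 HDF5), with QIIME-style taxonomy
strings; networks are written as GraphML and edge-list TSV.

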