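# larvaldrift

Tools for archipelago-scale marine biogeography: how far can short-lived
planktonic larvae actually travel between islands, do the resulting
connectivity patterns organize the islands into oceanographic clusters, and
how many independently evolving lineages do the sampled individuals
represent?

The package was built around the study system of keyhole limpets
(Fissurellidae) in a remote volcanic archipelago — sessile rocky-shore
gastropods whose larvae drift passively for days — but every stage is
generic: it works on any gridded current field, coastal-cell table,
island connectivity matrix, or ultrametric tree.

## What it does

- **Synthetic seascapes** (`seascape`): archipelagos of coastal cells with
  substrate labels (rock/sand/both), and divergence-free, time-varying
  current fields built from a streamfunction — so trajectories have analytic
  oracles. Per-island shore substrate composition.
- **Lagrangian dispersal** (`lagrangian`): seasonal 12-hourly releases from
  rocky coastal cells, RK4 advection with bilinear/linear interpolation,
  landing on first shore contact, events with drift time and great-circle
  distance.
- **Connectivity** (`connectivity`): cell- and island-level directed
  probability matrices `P[i][j] = P(larva from i lands on j)`, dispersal
  summaries, and reader/writer for the published matrix layout. The printed
  4-day and 30-day island matrices for the nine Cape Verde islands ship as
  fixtures.
- **Network clustering** (`network`): symmetrization, percolation-threshold
  pruning (weakest links removed while the network stays connected),
  leading-eigenvector community detection with Kernighan–Lin refinement,
  weighted modularity

  `Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j)`,

  and a seeded permutation test of clustering significance.
- **GMYC species delimitation** (`gmyc`): the single-threshold general mixed
  Yule-coalescent model — branching rates `b = λ n^p` between species and
  `b = λ Σ_j (n_j(n_j−1))^p` within them, threshold profiled over node
  heights — with a likelihood-ratio test against the single-process null and
  a Yule-over-coalescent tree simulator for parameter-recovery testing.
- **Supporting statistics** (`stats`): nested-model likelihood-ratio test
  from printed −lnL values; Pearson richness–substrate correlation.

A thin CLI (`larvaldrift seascape | simulate | connect | cluster | delimit |
stats | fixtures`) wraps the library and writes a JSON manifest (config,
seed, version, wall time) next to every output, so runs are reproducible
from their manifests. The `examples/` directory holds one short narrative
script per capability.

## Worked example

Clustering the packaged printed 4-day island connectivity matrix
(`examples/03_network_clustering.py`):

```
4-day PLD: percolation threshold tau = 4.80E-04, 3 communities, weighted modularity Q = 0.4202
  community 0: ['Maio', 'Santiago']
  community 1: ['Boavista', 'Ilheu Raso', 'Sal', 'Sao Nicolau']
  community 2: ['Santa Luzia', 'Santo Antao', 'Sao Vincente']
  permutation p-value (999 perms): 0.0540
```

Reading: after removing links weaker than 4.8×10⁻⁴ (the strongest pruning
that keeps the nine-island network connected), the leading-eigenvector
method finds three island groups with weighted modularity 0.42 — a strong
division by the usual Q > 0.3 convention — splitting the southern pair
(Santiago, Maio) from two northern groups. The permutation p-value asks how
often randomly re-wiring the same link weights does as well.

Delimiting species on a simulated 8-species tree
(`examples/04_gmyc_delimitation.py`):

```
tree: 80 tips, height 1.123
threshold at node height 0.0543
entities delimited: 8
lnL null = 731.56, lnL GMYC = 760.64
LRT: D = 58.17, df = 3, p = 1.45e-12
entity sizes: [10, 10, 10, 10, 10, 10, 10, 10]
```

The fitted threshold separates the 7 species divergences from the 72
within-species coalescences, recovers all 8 species with their 10 sampled
individuals each, and decisively rejects the single-lineage null.

And the founder-effect model comparison from printed likelihoods
(`examples/05_biogeo_stats.py`):

```
founder-effect LRT: D = 59.64, df = 1, p = 1.14e-14
```

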