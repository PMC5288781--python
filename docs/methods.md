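# Methods

`larvaldrift` implements the computational chain used to study archipelagic
endemism in sessile marine invertebrates with short-lived pelagic larvae:
synthetic seascapes, Lagrangian larval transport, island connectivity
matrices, network clustering of the resulting connectivity, GMYC species
delimitation, and two supporting statistics. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic generators do and do not emulate.

## Synthetic seascapes

**Current fields.** Velocities derive from a streamfunction
`psi = -u0*y + v0*x + sum_k A_k exp(-r_k^2 / 2 sigma_k^2)` evaluated at cell
centers on a local flat metric (metres, with the zonal scale fixed at the
grid's mid-latitude). Each Gaussian bump is a mesoscale gyre whose azimuthal
speed peaks at the prescribed value one radius from the center
(`A = peak * sigma * sqrt(e)`); the linear term is a uniform background
drift. Velocities are obtained by *central finite differences* of `psi`
rather than its analytic curl: the cross-derivative terms then cancel
identically, so the discrete divergence at interior cells is exactly zero
(up to rounding) instead of merely O(h^2). This gives the advection tests an
analytic oracle — particles in a single-gyre field follow closed
streamlines, so their radius from the gyre center must be conserved.
Optional seeded Gaussian noise (per time step and cell) makes the field
time-varying at the cost of exact non-divergence; zeroing velocities over
land likewise breaks the cancellation in the land-adjacent stencils, which
is why the divergence invariant is asserted on interior ocean cells away
from shore.

Defaults for the worked examples and CLI (one gyre of 0.3 degrees radius and
0.5 m/s peak speed, mean flow (0.1, 0.05) m/s or weaker, no noise) sit in
the range of observed subtropical eastern-Atlantic surface currents; peak
speeds above 3 m/s are rejected as implausible.

**Archipelagos.** Islands are non-overlapping disks of land cells placed by
rejection sampling (an explicit error names the constraint after a bounded
number of retries). Coastal cells are the ocean cells 8-adjacent to land, so
every island carries a closed ring of landing sites. Substrate labels
(`rock`, `sand`, `both`) are drawn i.i.d. from a configurable mix; the
default 0.5/0.3/0.2 reflects a rocky-dominated volcanic shoreline. The
substrate summary reports per-island counts, percentages (always summing to
100), and coastline "amounts" obtained by multiplying counts by a cell
length — by default the zonal great-circle extent of one grid cell at the
island's mean latitude.

**What the generator does not emulate:** real coastline geometry and
fractality, bathymetry, tides, wind-driven surface drift, and mesoscale
variability beyond the prescribed gyres. Tests passing on these seascapes
therefore validate the machinery (integration accuracy, bookkeeping,
aggregation), not any claim about a specific real archipelago.

## Lagrangian transport

Particles are released from the centroids of eligible coastal cells —
rocky-reef cells (`rock` or `both`) by default — every `interval_hours`
(default 12 h) through a release season (default August–December, in a fixed
365-day calendar) for a configurable number of years. Positions are
integrated with classical RK4 at a default 1-hour step, with bilinear
spatial and linear temporal interpolation of the velocity field; m/s convert
to degrees/hour via the local metric (zonal component scaled by
cos(latitude)).

**Landing rule.** A particle lands the first time a step carries it into a
coastal or land cell *different from the cell it currently occupies*; a
landing in a land cell is snapped to the nearest coastal cell. Requiring a
cell *change* keeps the release cell itself from capturing its own particle
at t = 0 — a motionless particle in a zero field expires in place — while
still recording genuine returns (self-recruitment) when a particle leaves
and re-enters its natal cell. A release cell walled in by land lands its
particles after one step rather than erroring. Particles still adrift at the
maximum pelagic larval duration (PLD, default choices 4 and 30 days) expire,
as do particles leaving the model domain (flagged, not raised). Landing is
checked at step granularity: with fast flow over a fine grid a particle can
traverse more than one cell per step, so step length should be chosen
against the grid scale (at the default 1-h step and the grid resolutions
used here, displacements per step are below one cell).

Drift distance is the great-circle (haversine) separation between release
and landing positions, in km.

## Connectivity

Cell-level connectivity is the simple ratio landed(a→b)/released(a); each
released particle yields exactly one event (landed or expired), so release
counts are recoverable from the event list itself. Island-level
connectivity is the *mean over the source island's release cells* of each
cell's total probability of landing anywhere on the destination island
("mean connectivity"); pooling particle counts instead (weighting cells by
releases) is available behind a flag. The diagonal is left undefined — the
published tables do the same — and self-recruitment is instead visible in
the event lists. Dispersal summaries (max/mean/SD of distance, per-pair
probability, and drift time) cover landed events whose destination differs
from the source cell.

Matrices are stored as labelled delimited text with an em dash on the
diagonal, the layout of the published tables; probabilities are held at full
precision and formatted like the printed tables (`%.2E`) only on export. Two
printed 9-island matrices (4-day and 30-day PLD) ship as packaged fixtures
and load via `load_table2()` / `load_table3()`.

## Network clustering

The directed matrix is symmetrized — arithmetic mean of the two directed
probabilities by default, as the least biased convention where the source
analysis does not state one; `max` and `min` are available. The percolation
threshold is the largest weight `tau` such that keeping edges with weight
>= `tau` leaves the island network connected (found by a sweep over the
distinct weights); pruning keeps the network connected by default, with the
"just past disconnection" variant behind a flag. The full pipeline records
symmetrization, pruning rule, threshold and modularity in every result and
run manifest, because the partition and its modularity are sensitive to
these choices.

Communities come from the leading-eigenvector method on the weighted
modularity matrix `B = A - k k^T / 2m`: recursive bisection by the sign of
the dominant eigenvector of the generalized modularity matrix of each
community (zero components join the positive side for determinism), with
candidate splits also seeded from the next-leading eigenvectors. Each
candidate split is polished with the Kernighan–Lin style fine-tuning passes
of the original method (every vertex moved once per pass, best prefix kept),
a split is accepted only if it increases Q, and a final multiway KL
refinement — also restarted from the all-singletons partition — polishes the
result. The refinement stages matter: plain sign-splitting alone misses the
maximum-modularity partition on a fifth of small random graphs, while the
full procedure matches exhaustive search on the <= 8-node suites used in the
tests. An edgeless graph yields singleton communities with Q defined as 0.

Clustering significance is a permutation test: the observed multiset of edge
weights is placed on uniformly chosen distinct node pairs (weights
preserved, topology randomized), the pipeline's modularity is recomputed,
and the add-one p-value `(1 + #{Q* >= Q}) / (n_perm + 1)` is reported
(default 10,000 permutations, seeded). Shuffling weights with the topology
held fixed was rejected as a null because it cannot detect structure carried
by the arrangement of links: permuting the equal weights inside two disjoint
cliques never changes Q, so that null would find the most clustered
configuration imaginable "not significant".

**Known limitation.** Running this pipeline on the packaged printed matrices
gives Q = 0.420 with three communities (4-day) and Q = 0.483 with three
communities (30-day). These are the pipeline's honest outputs for the
printed data; published figures derived from the same study system report
lower modularities and, for the 30-day network, two clusters, which this
pipeline does not reproduce under any of the exposed symmetrization,
pruning, or weighting variants — the published network stage evidently used
additional unpublished inputs or an unstated aggregation. The variants are
all exposed and recorded so users can state exactly which graph their
numbers describe.

## GMYC species delimitation

The single-threshold GMYC model places a time `T` on an ultrametric tree of
individuals: nodes older than `T` are between-species diversification
events, younger nodes are within-species coalescences. Waiting times between
branching events are exponential with class rates

    b_div,i  = lambda_div  * n_div,i ^ p_div
    b_coal,i = lambda_coal * sum_j ( n_ij (n_ij - 1) ) ^ p_coal

where `n_div,i` counts species lineages in interval i (all lineages above
`T`; constant once the threshold is passed) and `n_ij` the lineages of
cluster j; clusters with a single lineage contribute nothing. The exponents
relax the strict Yule (`p = 1`) and neutral-coalescent (`p = 1`) scalings.

**Interval convention.** The likelihood is a product over the n−1 intervals
bounded by the branching events and the present; interval i contains i+1
lineages and is *associated with the node at its rootward end*, whose class
supplies the event factor, while both classes contribute to the survival
term. This is the standard coalescent convention (the interval with k
lineages ends, looking rootward, in the coalescence at rate ~k(k−1)), and it
is the only association that is well defined here: tying intervals to the
event at their tipward end would hand the first sub-threshold branching an
event rate of zero (all clusters still being singletons in that interval),
sending every candidate threshold's likelihood to −infinity. Under the
rootward convention the all-diversification candidate reproduces the
single-process null `b_i = lambda * n_i ^ p` term for term, so the
alternative's maximized log-likelihood can never fall below the null's — an
invariant the tests assert. One consequence: the tip interval carries an
event factor, so the pure-Yule rate MLE is inflated by (n−1)/(n−2),
negligible at the tree sizes used.

**Fitting.** For each candidate threshold (one per observed node height,
ties and zero waiting times first perturbed by 1e−9 x tree height with a
fixed seed), the rate parameters are profiled out analytically
(`lambda_hat = #events / sum(rate_shape_i * x_i)`, clipped to
[1e−10, 1e6]) and the two exponents are maximized by bounded L-BFGS-B in
(−5, 5) from 5 seeded starts — the profile over thresholds is ragged, so a
single start is not trustworthy. Entities at the chosen threshold are the
tip sets of the subtrees crossing it plus the singletons branching off above
it; they always partition the tips.

The likelihood-ratio test against the single-process null uses
`D = 2 (lnL_GMYC − lnL_null)` with a chi-square reference on df = 3 by
default (threshold plus the extra rate and exponent); df = 2 is available
since implementations differ, and the df used is carried in every result.
On simulated single-population coalescent trees the df = 3 test rejects at
~4% for nominal 5%, i.e. approximately calibrated despite the threshold
maximization.

**Simulator.** `simulate_gmyc_tree` grafts standard Kingman coalescent
subtrees onto a Yule species tree (waiting time with k lineages ~
Exp(k*lambda)); all subtrees share one scale factor chosen so the deepest
within-species coalescence sits at `within_species_height_scale` times the
shallowest species divergence (default 0.05, i.e. a 20-fold depth
separation). `n_species = 1` returns a pure coalescent tree, the null case
for calibration. The test suite sizes — 8 species x 10 tips over 50
replicates for delimitation recovery, 20-tip single-population trees over
200 replicates for type-I calibration — were chosen as the smallest designs
at which the recovery and calibration claims are meaningfully testable. The
simulator draws clean ultrametric trees: it does not emulate phylogenetic
estimation error, rate variation, or non-contemporaneous sampling, so
recovery rates on it bound what the model can do with perfect trees, not
what it does after real tree inference.

## Supporting statistics

The nested-model LRT takes two negative log-likelihoods, forms
`D = 2(−lnL_null − (−lnL_alt))`, and evaluates the chi-square upper tail in
full double precision (`chi2.sf`; no underflow to zero above ~1e−300).
Inverted inputs (alternative fitting worse) are flagged and reported with
p = 1 rather than raising. The richness–substrate correlation is a Pearson
r with the two-sided t-test `t = r * sqrt(df / (1 − r^2))`, df = n − 2;
two-sided because no direction is privileged a priori.

## Numerical conventions and degenerate inputs

- All generators and stochastic routines take explicit integer seeds and are
  bit-reproducible for a fixed seed.
- Ultrametricity is enforced within a relative tolerance of 1e−6 x tree
  height; violations name the worst tip pair. Polytomies are resolved with
  zero-length branches and then perturbed like other ties.
- Sign ties in the eigenvector split go to the positive side; community ids
  are renumbered in order of first appearance, so partitions are
  deterministic.
- Earth is a sphere of radius 6371 km both in the degree/metre conversion
  and in haversine distances.
- Empty event lists, all-self-recruitment event lists, edgeless graphs, and
  degenerate thresholds return well-defined values (NaN summaries, singleton
  partitions with Q = 0, entity counts at the boundary) instead of raising.
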