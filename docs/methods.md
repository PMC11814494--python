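# Methods

## The procedure

`mdsclust` clusters microbiome samples in two steps. First the n×P table of
relative abundances is reduced to an n×n pairwise distance matrix under a
compositionality-aware metric, and that matrix is denoised by classical
multidimensional scaling (MDS/PCoA): the squared distances are
double-centered into a Gram matrix B = −½L(D∘D)L, B is eigendecomposed, and
the samples are embedded on the leading r strictly positive eigenvalues,
Y = Q_r Λ_r^{1/2}. Second, PAM/k-medoids clusters the embedded coordinates
under Euclidean distance, with the number of clusters either supplied or
estimated (silhouette index, gap statistic, or prediction strength). The
baseline comparator — PAM and the selectors operating directly on the raw
distance matrix — is available by switching `use_mds` off.

A note on the centering step: classical MDS is defined on *squared*
distances; using unsquared distances would break the exact-recovery
property (a Euclidean distance matrix must re-embed to itself). This
package therefore squares before centering. Negative eigenvalues, which
necessarily appear for non-Euclidean dissimilarities like Bray–Curtis and
UniFrac, are excluded from the embedding rather than repaired by a
Cailliez/Lingoes shift: the leading positive part of the spectrum is what
carries the cluster signal, and the shift would distort it.

## Distance metrics

* **Bray–Curtis** Σ|a−b| / Σ(a+b) and **binary Jaccard** 1 − |A∩B|/|A∪B|
  on presence sets; both on the simplex, no tree.
* **UniFrac family** on a rooted phylogeny. Branch "abundance" for a sample
  is the total proportion on the leaves below the branch, accumulated by a
  single post-order pass (O(P) per sample; the full matrix is two matrix
  products plus an O(n²E) reduction). Unweighted UniFrac is the fraction of
  branch length leading to lineages present in exactly one of the two
  samples; weighted UniFrac is implemented in its normalized form
  Σ l|p_a−p_b| / Σ l(p_a+p_b) so all metrics share the [0,1] scale;
  generalized UniFrac weights each branch by (p_a+p_b)^α, default α = 0.5,
  and recovers the weighted form exactly at α = 1.
* **CLR**: Euclidean distance after centering each log-composition
  (delegated to scikit-bio). **PhILR**: Euclidean distance between the ILR
  balances whose sequential binary partition is the phylogeny; each
  internal node contributes sqrt(rs/(r+s))·ln(g(numerator)/g(denominator)).
  The contrast matrix is orthonormal on the clr hyperplane, so PhILR
  distances equal Aitchison distances exactly (this isometry is tested).
  Multifurcations are resolved deterministically with zero-length edges;
  no taxon or branch-length weighting is applied.
* **Zeros**: the log-ratio metrics require strictly positive input. The
  policy is a pseudocount of 0.5 added to raw counts before closure; tables
  that arrive as proportions receive 0.5/virtual_depth (default depth
  10,000) and are re-closed.

## PAM

Kaufman–Rousseeuw BUILD+SWAP on a precomputed distance matrix, fully
deterministic (all ties break to the lowest sample index, so no seed is
involved and outputs are bit-reproducible). Single-start BUILD+SWAP is a
local search and demonstrably can stall above the global optimum even at
n = 4; on small instances (n ≤ 30), where it costs little, the search is
restarted from every sample as the forced first BUILD medoid and the best
local optimum kept. In a 3,000-instance check against exhaustive medoid
enumeration (n ≤ 10) the multi-start never missed the optimum. Large
instances use the single classical start; cluster labels are canonicalized
by first appearance.

## Cluster-number selection

* **Silhouette (SI)**: mean silhouette width (scikit-learn, precomputed
  distances; singletons contribute 0), maximized over k = 2..k_max. After
  MDS the widths use Euclidean distances in the embedding — the geometry
  silhouette assumes — while in raw mode they use the original metric.
* **Gap statistic**: W_k = Σ_r D_r/(2n_r) with D_r the within-cluster sum
  of squared pairwise distances; B reference datasets are drawn uniformly
  over the per-coordinate bounding box of the (embedded) data, and the
  selected k is the smallest with Gap(k) ≥ Gap(k+1) − s_{k+1},
  s = sd·sqrt(1+1/B). In raw-distance mode the observed W_k uses the
  supplied distances while references are drawn over the bounding box of
  the full principal-coordinate embedding — the gap statistic has no exact
  definition for arbitrary dissimilarities, and this is the least-surprising
  extension. (An alternative — permuting each embedded coordinate — was
  rejected: when one coordinate dominates, the permutation reproduces the
  data and the gap vanishes identically.) Note the 1-SE stopping rule is
  only informative when each k below the truth captures real structure:
  four mutually equidistant clusters stall it at k = 1 by symmetry, which
  is why the selector fixtures use hierarchically arranged groups.
* **Prediction strength (PS)**: random half-splits, PAM on both halves,
  test samples assigned to the nearest training medoid; ps(k) is the worst
  per-test-cluster fraction of co-clustered pairs that the training rule
  also co-assigns, averaged over 10 splits; the largest k with mean
  ps ≥ 0.8 is chosen, ps(1) ≡ 1.

Defaults: k_max = 10, B = 50, threshold 0.8, 10 splits; all selector
randomness is seeded.

## Synthetic data

The simulators generate the four-cluster study design: 4 × 100 samples,
P = 856 OTUs, sequencing depths from a truncated normal (mean 10,000,
sd 15,000, bounds [2,000, 50,000], inverse-CDF sampling, rounded).
Per-cluster compositions come from either a Dirichlet-multinomial
(concentration α = π(1−θ)/θ) or a logistic-normal multinomial (logit-scale
Gaussian with the last OTU as additive-logistic reference, AR(1) covariance
τ²ρ^|i−j|, defaults τ = 2, ρ = 0.2).

The baseline composition is synthetic: log-normal OTU magnitudes closed to
proportions, ranked and split into 20 equal-size abundance groups (group 1
most abundant). Cluster differentiation is confined to an OTU subset —
all OTUs of the three most-abundant groups ("common lineage"), of the three
least-abundant groups ("rare lineage"), or 20 OTUs from each of three
random groups (60 in total) — scaled by a signal-strength multiplier
(DM default 1.4) or a logit-mean factor (LN defaults 2.75/5.8/3.6 for
common/rare/random). Because a single multiplier cannot make three extra
clusters mutually distinct, lineage modes apply it with exponents +1, −1
and +2 for clusters 2–4, and random mode draws an independent subset per
cluster. A random binary phylogeny (Exponential(1) branch lengths) places
group-mates as adjacent leaves so lineage subsets are phylogenetically
coherent. All randomness flows from one master seed through named
SeedSequence spawns; a dataset is a pure function of its design.

**Calibration of the baseline.** The two free noise parameters — the DM
dispersion θ = 0.001 and the log-normal abundance spread σ = 0.5 — were
fixed once so that the stated signal strengths land in the intended
regimes: no signal (multiplier 1.0) gives chance-level recovery (ARI ≈ 0),
strong signal (3.0, random subset) gives near-perfect recovery
(ARI ≥ 0.9), and the sparse rare-lineage setting at 1.4 sits in the
weak-separation regime where raw-distance PAM fails (ARI ≈ 0.02) but
MDS-denoised PAM recovers substantial structure (ARI ≈ 0.6). Larger θ or a
steeper abundance tail pushes the rare-lineage fraction of community mass
so low that every method collapses to chance and the regimes become
indistinguishable. With σ = 0.5 the three rarest groups carry roughly 2% of
total abundance — sparse, but not vacuous.

**What the generator does not emulate.** Real tables have stronger
zero-inflation, taxon-taxon correlation beyond the AR(1) stand-in,
phylogenetic signal in abundance (here only group-level), and uneven group
sizes. Passing benchmarks on these simulations therefore demonstrates the
method's behaviour under its intended sparse-signal mechanism, not its
performance on any particular real cohort. In the LN rare-lineage mode the
exponent pattern drives the subset essentially to zero abundance in two of
the perturbed clusters, which makes those clusters hard to tell apart —
a known degeneracy of applying one multiplicative factor on the logit
scale.

## Evaluation and benchmark

Agreement with the planted truth is measured by the Hubert–Arabie adjusted
Rand index (scikit-learn; an explicit pair-counting oracle backs it in the
tests). The benchmark loop pairs replicates — every grid cell (metric ×
selector × MDS on/off × rarefied or not) sees the same simulated dataset —
which removes simulation noise from the MDS-vs-PAM comparison. Rarefaction
subsamples each sample without replacement (multivariate hypergeometric) to
the minimum sample depth by default.

## Numerical choices and edge cases

* Eigen-solver: `scipy.linalg.eigh`; eigenvector signs fixed by making the
  largest-magnitude loading positive, so output files are reproducible.
* Eigenvalue-ratio search range k_max = min(#positive−1, n/2).
* Proportions are validated to 1e-9; rows within 1e-6 of 1 are re-closed
  silently; anything further off is an error.
* Degenerate inputs: all-identical samples give a zero Gram matrix and a
  single constant coordinate; the gap statistic reports k = 1 when
  within-cluster dispersion vanishes; PAM with k = n returns every sample
  as its own medoid with objective 0; a medoid always belongs to its own
  cluster even when duplicate points tie at distance zero.
* Branches with missing lengths are a hard error everywhere (no silent 0).

## Problem sizes used in the test suite

Method-level checks run at the full study geometry (400 × 856): 50 paired
replicates for the sparse-signal comparison, 50 replicates for
strong-signal recovery with silhouette selection, and 100 seeded runs per
selector-sanity check on planted blobs. Unit-level oracle checks
(UniFrac branch enumeration, exhaustive PAM, pair-counting ARI, MDS
recovery) use small instances where exhaustive enumeration is feasible.

## Known limitations

* The gap statistic inherits the blind spot of its 1-SE rule under
  symmetric nested structure (see above).
* PhILR weighting variants (taxon weights, branch-length scaling) are not
  implemented; the plain ILR balances on the tree partition are.
* UniFrac is computed densely; the implementation targets hundreds of
  samples, not tens of thousands.
* Prediction strength with the conventional 0.8 cutoff is conservative in
  weak-signal regimes (it tends to underestimate k); no cutoff tuning is
  attempted.
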