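# mdsclust

MDS-enhanced distance-based clustering for microbiome compositional data.

## The problem

Clustering microbiome samples (e.g. finding enterotypes) is usually done with
distance-based methods such as PAM/k-medoids on a microbiome-aware
dissimilarity — Bray–Curtis, UniFrac, or a log-ratio (Aitchison-geometry)
distance. These methods struggle in the **sparse-signal scenario**: when the
true cluster structure is driven by a small subset of the hundreds of OTUs in
the table, the informative differences are diluted by noise from the many
uninformative OTUs, and pairwise distances lose their discriminative power in
high dimension.

`mdsclust` implements a two-step remedy: **denoise first with classical
multidimensional scaling (MDS / principal coordinates analysis), then
cluster the low-dimensional coordinates with PAM.** Given an OTU table
`X` (n samples × P OTUs, normalized to proportions):

1. Compute the pairwise distance matrix `D(X)` under a chosen metric `d`.
2. Double-center the squared distances: `B = −½ L (D∘D) L`, `L = I − 11ᵀ/n`.
3. Eigendecompose `B = Q Λ Qᵀ`.
4. Keep the top `r` strictly positive eigenvalues (`r` chosen by the
   eigenvalue-ratio rule, `argmax_k λ_k/λ_{k+1}`) and embed
   `Y = Q_r Λ_r^{1/2}`.
5. Run PAM on the Euclidean distances of `Y`, minimizing
   `Σᵢ min_j ‖yᵢ − c_j‖`, with the number of clusters `k` fixed by the user
   or selected by the silhouette index, gap statistic, or prediction
   strength.

The package ships seven distance metrics (Bray–Curtis, binary Jaccard,
unweighted / weighted / generalized UniFrac, CLR, PhILR), the three
cluster-number selectors, rarefaction, two generative simulators
(Dirichlet-multinomial and logistic-normal multinomial) with
sparse-subset cluster differentiation, and an ARI-based benchmark loop
comparing MDS+PAM against PAM on the raw distances.

## Worked example

Simulate a hard sparse-signal dataset (400 samples × 856 OTUs, four clusters
differing only on the rare-lineage OTU subset at signal strength 1.4), then
cluster it:

```python
from mdsclust import MDSClusterModel, SimDesign, simulate, adjusted_rand_index

design = SimDesign(scenario="dm", subset_type="rare_lineage",
                   signal_strength=1.4, seed=7)
sim = simulate(design)

model = MDSClusterModel(sim.table, metric="bray_curtis", use_mds=True)
res = model.fit(selector="si", k_max=8)
print(res.summary())
```

```
MDS-enhanced PAM clustering
===========================
samples:            400
OTUs:               856
distance metric:    bray_curtis
MDS:                on (rank 1, eigenvalue_ratio)
top eigenvalues:    0.6479, 0.356, 0.3533, 0.3442, 0.3388
number of clusters: 2 (si)
selector curve:     k=2: 0.611, k=3: 0.592, k=4: 0.557, k=5: 0.542, k=6: 0.532, k=7: 0.530, k=8: 0.531
cluster sizes:      1: 212, 2: 188
PAM objective:      7.1172
```

The silhouette curve is nearly flat — the signature of a weak-separation
regime — and the selector merges the four planted clusters into two.
Against the known truth:

```python
print(adjusted_rand_index(sim.truth, res.membership))              # 0.401
pam_only = MDSClusterModel(sim.table, metric="bray_curtis",
                           use_mds=False).fit(k=4)
print(adjusted_rand_index(sim.truth, pam_only.membership))         # 0.015
```

Even with the merged `k`, the MDS-denoised partition recovers substantial
structure (ARI 0.40; 0.65 when `k=4` is supplied), while PAM on the raw
Bray–Curtis matrix is essentially random (ARI 0.015): the sparse signal is
buried in the full-dimensional distances but dominates the leading
principal coordinates.

## Command line

```sh
mdsclust simulate --scenario dm --subset rare --signal 1.4 --seed 7 --outdir data/
mdsclust run --otu data/otu_table.tsv --distance bc --select si \
             --labels data/truth.tsv --out results/run1
mdsclust bench --scenario dm --subset rare --signal 1.4 \
               --metrics bc,clr --selectors oracle --reps 50 --out bench.csv
```

`run` writes a membership TSV and a JSON diagnostics file (chosen k,
eigenvalues, selector curve, full configuration); `bench` writes a
long-format CSV of per-replicate ARIs for every (metric, selector, MDS
on/off, rarefaction) cell.

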