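# ctascore

Marker-driven, per-cluster cell-type annotation for single-cell RNA-seq.

After a scRNA-seq experiment has been clustered (e.g. by graph clustering on
a reduced-dimension embedding), each cluster still needs a cell-type label.
The conventional route — eyeballing violin and feature plots for every marker
of every candidate type — is slow and subjective, especially with dozens of
clusters. `ctascore` implements the **Cell Type Activity (CTA)** score, a
semi-automatic alternative: given a genes × cells expression matrix, the
cluster membership of each cell, and a user-supplied marker gene list per
cell type, it produces for each cell type a probability profile over the
clusters and annotates every cluster whose score clears a user-chosen cutoff.

## The score

For one cell type with *N* marker genes over *K* clusters:

1. **Profile.** Tabulate the cluster *median* expression of each marker
   (an *N × K* matrix) and normalize each row to sum to unity, giving
   *p*<sub>ik</sub>.
2. **Weight.** Weight each marker by an inverted Gini impurity,
   *W*<sub>i</sub> = 1 + Σ<sub>k</sub> *p*<sub>ik</sub>², so a marker
   expressed specifically in one cluster gets the maximal weight 2 and a
   marker spread uniformly gets the minimal 1 + 1/*K*.
3. **Score.** Score each cluster with the weighted cluster-*mean* marker
   expression, *S*<sub>k</sub> = Σ<sub>i</sub> *Ē*<sub>ik</sub>·*W*<sub>i</sub> / *N*³.
4. **Probabilities.** Normalize *S*<sub>1..K</sub> to sum to one.

Steps 1–4 are repeated for each of the *C* cell types, yielding a *C × K*
CTA matrix. Clusters scoring strictly above a cell type's cutoff are
annotated with it; the cutoff is chosen per type from the cumulative
distribution of that type's scores (the package emits both the empirical
curve and a moment-fitted normal CDF). Because step 4 cancels any
per-cell-type constant, annotations are invariant to the *N*³ convention and
to global rescaling of the expression values.

Cell-level QC precedes scoring: cells with a mitochondrial fraction above
25% are removed (strictly above), and only cells detecting between 200 and
5,000 genes (inclusive) are kept. Both thresholds are configurable.

## Worked example

Simulate a small dataset with four planted cell types (10 markers each,
eight-fold marker up-regulation, 30% dropout), then run the full
QC → score → annotate pipeline against the generated truth:

```sh
ctascore simulate --out-dir sim --seed 11
ctascore pipeline --expr sim --clusters sim/clusters.tsv \
    --markers sim/markers.csv --out-dir run \
    --min-features 0 --truth sim/truth.tsv
```

The pipeline logs end with:

```
INFO ctascore: recovery rate vs truth: 1.000
INFO ctascore: pipeline outputs in run
```

`run/cta_matrix.tsv` holds the 4 × 4 CTA matrix; for seed 11 its first row is

```
cell_type   cluster0   cluster1   cluster2   cluster3
type0       0.730...   0.087...   0.099...   0.084...
```

i.e. the markers of `type0` concentrate ~73% of their probability mass on
`cluster0`, its planted cluster, and every cluster is annotated with its true
type (`run/annotation.tsv`); the recovery rate of 1.000 means all 4 clusters
were labelled correctly. `run/summary.tsv` counts member cells and expressed
genes per annotated type. (`--min-features 0` disables the feature-count
filter, sized for real transcriptomes, on this 240-gene toy.) Use
`ctascore plot-cdf` to draw the per-type score CDFs that guide cutoff
selection on real data, and `ctascore <cmd> --help` for every option.

The same operations are available as a library:

```python
from ctascore import SimConfig, simulate, compute_cta_matrix, assign_types

expr, clusters, truth = simulate(SimConfig(seed=11))
m = compute_cta_matrix(expr, clusters, truth.marker_catalog)
result = assign_types(m)          # default cutoff 0.5
print(result.cluster_to_type)     # {'cluster0': 'type0', ...}
```

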