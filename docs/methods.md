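# Methods

## The model

`ctascore` annotates *clusters*, not individual cells. It assumes that
clustering has already grouped transcriptionally similar cells and that the
user can name, for each candidate cell type, a handful of genes whose
expression is characteristic of that type. The Cell Type Activity (CTA)
score then asks, for each cell type independently: *over which clusters is
this type's marker expression concentrated?*

For a cell type with markers *i* = 1..*N* and clusters *k* = 1..*K*:

- **p<sub>ik</sub>** — the cluster *median* expression of marker *i*,
  row-normalized so Σ<sub>k</sub> p<sub>ik</sub> = 1. The median is robust
  to the heavy right tail and technical zeros of single-cell counts, so the
  profile reflects where a marker is *typically* expressed.
- **W<sub>i</sub> = 1 + Σ<sub>k</sub> p<sub>ik</sub>²** — an inverted Gini
  impurity. Ordinary Gini impurity (1 − Σ p²) is minimal when a
  distribution is concentrated in one class; inverting it rewards
  concentration, so a cluster-specific marker gets the maximal weight 2
  while an uninformative, uniformly spread marker gets the minimal
  1 + 1/*K*. These bounds are attained exactly at one-hot and uniform
  rows and are asserted as a property test.
- **S<sub>k</sub> = Σ<sub>i</sub> Ē<sub>ik</sub> W<sub>i</sub> / N³** — the
  specificity-weighted cluster *mean* expression, where Ē<sub>ik</sub> is
  the arithmetic mean of marker *i* over cluster *k*'s cells. The median
  drives specificity (via W) and the mean drives magnitude; the two
  statistics are kept distinct deliberately, since they play different
  roles.
- The S<sub>k</sub> are normalized to sum to one and read as a probability
  profile of the cell type over clusters.

Annotation inverts the per-type view: a cluster's candidate types are those
whose normalized score at that cluster is *strictly above* the type's
cutoff; the highest score wins among several candidates (ties broken by
catalog order and logged), and a cluster with no candidate is reported as
`unassigned`. The method is semi-automatic by design: cutoffs are chosen by
the user per cell type from the cumulative distribution of the normalized
scores. Both the empirical CDF and a normal CDF fitted by moments are
emitted, since either curve can guide the choice; a single
`default_cutoff` (0.5 unless overridden) supports non-interactive runs.

## Numerical conventions

- **N³ denominator.** The denominator of S<sub>k</sub> is a per-cell-type
  constant and cancels when scores are normalized to probabilities, so the
  choice of convention cannot change any annotation. This is asserted as a
  test (replacing N³ by 1 leaves normalized scores unchanged to 1e-9).
  Raw scores are still available (`--raw-out`) but are flagged as
  denominator-convention-dependent.
- **Zero rows.** A marker whose median is zero in every cluster gets the
  uniform profile (weight 1 + 1/*K*, the least informative); its mean
  contribution is typically negligible anyway, so the convention only
  avoids division by zero. Likewise a cell type whose raw scores are all
  zero yields the uniform probability profile, with a warning.
- **Absent markers** are dropped and *N* reduced to the markers actually
  found; keeping them would deflate that type's raw scores by a constant
  and (unlike the denominator) this constant differs per type. A cell type
  with *no* marker found is excluded from the matrix and reported, never
  silently scored.
- **Medians** with an even cell count are the midpoint of the two central
  values (the standard convention).
- **Determinism.** Accumulations run in fixed (marker-ascending) order;
  identical inputs give byte-identical TSV outputs, which the CLI test
  suite asserts.
- Gene matching between marker lists and the expression matrix is exact
  and case-sensitive (gene symbols only): silent case-folding can hide
  species mix-ups such as mouse `mt-` vs human `MT-` prefixes. Duplicate
  symbols in a features file are disambiguated with `.1`, `.2` suffixes
  in file order.
- The score is scale-invariant, so raw or log-normalized input works
  equally; log-normalized values are recommended since the mean Ē is
  otherwise dominated by the count scale of highly expressed markers.
  Negative (e.g. z-scored) input is rejected.

## Quality control

Two cell-level filters run before scoring, with these defaults:

| parameter | default | meaning |
|---|---|---|
| `mito_max_fraction` | 0.25 | remove cells with mitochondrial fraction **strictly above** this |
| `min_features` / `max_features` | 200 / 5000 | keep cells whose detected-gene count lies in this **inclusive** range |
| `mito_prefix` | `mt-` | gene-id prefix marking mitochondrial genes (mouse; use `MT-` for human) |

The asymmetric boundary conventions (strict vs inclusive) follow the usual
phrasing of these filters — "more than 25% removed", "within 200–5,000
kept" — and are pinned by unit tests on cells sitting exactly on each
boundary. Gene-level filtering is opt-in (`drop_unexpressed_genes`,
`min_cells_per_gene`) and never silent: upstream toolkits commonly apply an
implicit minimum-cells-per-gene cut, so post-QC gene totals from other
pipelines are not reproducible from cell filters alone and this package
does not claim to match them.

## Synthetic data

`simdata` generates seeded count matrices with planted structure: every
gene draws negative-binomial (gamma-Poisson) counts with baseline mean
`baseline_mean` and shape `dispersion` (variance μ + μ²/θ), a cell type's
markers are up-regulated by `fold_change` in that type's clusters, and
independent Bernoulli dropout zeroes each entry with probability
`dropout_rate`. Defaults: 4 types × 10 markers (the size of typical curated
marker lists), 1 cluster per type, 50 cells per cluster, 200 background
genes, baseline mean 2.0, fold change 8, dispersion 2.0, dropout 0.3 —
a strong-signal regime in which annotation must saturate (recovery 1.0),
which the acceptance suite asserts end-to-end through the CLI. At
`fold_change=1` the markers are exchangeable with background and the score
matrix is near-uniform (max score < 3/K in ≥90% of seeded replicates);
recovery is non-decreasing in fold change on average across seeds.

What the generator deliberately omits: library-size variation, gene–gene
correlation, batch effects, doublets, ambient RNA, and multiple types per
cluster boundary cases. Passing tests therefore demonstrate correctness of
the computation and robustness to count noise and dropout — not performance
on real tissues, where marker list quality and cluster granularity
dominate. Problem sizes in the test and acceptance runs (≤ 250 genes,
≤ 250 cells, ≤ 6 clusters; 50-replicate null sweeps) were chosen as the
smallest at which the distributional properties are stable.

## Design choices on genuinely open points

- **Conflict resolution** (a cluster above cutoff for several types) is by
  maximum normalized score, consistent with the probability reading of the
  scores; every conflict is recorded and logged rather than resolved
  silently.
- **Cutoff curves**: "cumulative distribution" can mean the empirical
  curve or a fitted normal; both are computed, the plot overlays them, and
  no decision in the package depends on the fitted parameters.
- **One input matrix** feeds both the median (step 1) and mean (step 3)
  summaries; maintaining two differently normalized matrices would invite
  inconsistency and nothing in the score's definition requires it.
- **Cluster labels are opaque strings** ordered by first appearance —
  numeric-looking labels are not reordered — so output column order is
  stable across toolkits.
- The `unassigned` sentinel participates in summaries as a footer (cluster
  and cell counts), not as a row of the per-type table.

## Limitations

- Clusters are the unit of annotation: a cluster mixing two real types is
  labelled with at most one (or none); re-clustering at finer resolution is
  the remedy, not per-cell scoring.
- Marker lists are trusted as given; no marker discovery or validation is
  attempted, and markers are matched by symbol only (no Ensembl-id
  support).
- No dropout imputation, doublet detection or ambient-RNA correction;
  these belong upstream.
- Raw scores are comparable across clusters within a cell type, but not
  across cell types with different marker counts — only the normalized
  profiles are cross-type comparable, and only as rankings.
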