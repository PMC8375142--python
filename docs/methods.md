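# Methods

`rnavista` automates the downstream stage of a bulk RNA-seq project —
exploration, visualisation and interpretation — starting from the
outputs of an upstream processing pipeline (normalized expression matrix
plus one differential table per contrast). It performs no alignment,
counting, normalization or differential testing of its own; those are
explicit non-goals and belong upstream.

## The master gene table

All inputs are joined on gene id (exact, case-sensitive) into one
per-gene table holding: annotation (symbol, chromosome), per-sample
expression, per-group means, per-gene z-scores, and per-comparison
log2 fold change, p, adjusted p and a significance call. Gene *symbols*
are used only when matching against gene-set (GMT) and regulator
(TRRUST) databases and are compared case-insensitively, since those
databases are keyed by symbol.

Calls: `up` iff adjusted p < threshold and log2FC > +t; `down` iff
adjusted p < threshold and log2FC < −t; `untested` when the gene is
absent from the differential table or its adjusted p is missing;
otherwise `ns`. Defaults are adjusted p < 0.05 and |log2FC| > 1,
overridable per comparison. Untested genes are excluded from
significant-gene analyses but remain part of the over-representation
universe, since they were measured.

Z-scores are computed per gene across **all** samples of the run (not
per workflow), with the sample standard deviation (ddof = 1);
zero-variance genes get an all-zero z row. Whether scoping z to a
workflow's groups would be preferable is genuinely open; the global
convention was chosen because one run has one master table and every
workflow then reads identical values. It is isolated in one place if a
different scope is ever wanted.

## Statistical core

* **Over-representation**: hypergeometric upper tail P(X ≥ k) for
  overlap k between a query of size n and a set of size K in a universe
  of size N, with Benjamini–Hochberg correction across all tested sets.
  The universe is background ∩ measured genes. Sets with fewer than 3 or
  more than 2000 universe members are not tested (standard practice;
  both bounds configurable). Enrichment ratio = (k/n)/(K/N).
* **Fisher exact (two-sided)**: sum of the probabilities of all tables
  with the observed margins whose probability does not exceed the
  observed table's — the classical definition.
* **BH**: step-up `q_(i) = min_{j≥i}(p_(j)·m/j)` capped at 1; missing
  p-values pass through untouched and do not count toward m.
* **Spearman**: Pearson correlation of mid-ranks.
* **UPGMA**: average-linkage agglomeration under the 1 − SCC distance.
  Rows with zero variance have no defined rank correlation; their
  distance to everything is fixed at 1 so clustering stays total.
  Heatmap leaf order uses *mean reordering*: at every internal node the
  subtree whose leaves have the lower mean of row-means is placed first.
  This operationalisation of mean reordering is a design choice (no
  canonical definition exists); it is deterministic and confined to one
  function.
* **PCA**: log10(x+1) transform, per-gene centring (no unit scaling),
  SVD of the samples × genes matrix; components 1..min(G, S−1) with
  percent variance summing to 100.

The exact tests and UPGMA stand on scipy; independent test oracles
(exact integer enumeration via binomial coefficients, a brute-force
recompute-every-average UPGMA, rank-then-Pearson) verify them to
1e−12.

## Upstream-regulator analysis

For each regulator with ≥ 3 universe targets, overlap between its
regulon and the comparison's significant genes is scored with the same
hypergeometric tail, BH-corrected across regulators. Separately, an
activation z-score is computed over significant targets with a *signed*
mode: a target is consistent if (Activation ∧ up) ∨ (Repression ∧ down)
and inconsistent for the opposite pairing;
z = (consistent − inconsistent)/√(consistent + inconsistent), 0 when no
signed targets. Unknown-mode targets count toward the overlap test but
never toward z (unweighted edges; edge weighting was considered and
rejected as the input format carries no weights). z > 2 declares
activation, z < −2 inhibition; a regulator can be significantly
enriched yet neither.

## Spatial (per-chromosome) analysis

Three two-sided Fisher families per comparison, each BH-corrected across
chromosomes: expression bias (expressed vs not, on vs off chromosome,
all annotated genes), differential bias (DE vs not, among expressed
genes — conditioning on expressed genes avoids rediscovering expression
bias), and direction bias (up vs down among DE genes). "Expressed"
means mean expression across samples ≥ 1.0 (configurable; there is no
canonical cutoff for normalized units). Genes without chromosome
annotation are excluded from all three families only.

## Differential expression signatures

Genes significant in ≥ 1 comparison are binned by their profile of calls
across comparisons (`untested` collapses to `ns`; at most 3^m − 1 bins
for m comparisons). Each bin's meta-gene is the per-sample **median** of
member-gene z-scores. Merging is agglomerative: while the best pair of
meta-genes has SCC strictly above the threshold, union their genes,
recompute the meta-gene *from the union's z-scores* (not by averaging
the two meta-genes — recomputation keeps the meta-gene a real summary of
its members), and repeat. Ties on the maximal SCC break by the
lexicographically first pair of profile labels. Signatures are ranked
by descending size. A threshold of 1 can never be exceeded, so it
yields zero merges — maximal resolution, one signature per profile.
Default threshold 0.9 (user-assignable; bins of size 1 are legal
signatures; no size floor). With fewer than 3 samples rank correlation
is meaningless and the bins are returned unmerged with a warning.

## Workflows, plot registry and script generation

Three workflow kinds — NE (expression overview/QC), DE (one contrast),
MDE (≥ 2 contrasts) — may appear any number of times, in any mixture,
per run. The plot-type registry is versioned in `registry.py` with
category sums pinned (QC 1, expression 7, DE 33, MDE 9 — 50 types) and
unit-tested; membership may only be adjusted within those sums.
"Top hits" is 5 everywhere; heatmaps use row z-scores with symmetric
colour limits at ±max|z| (correlation heatmaps use −1..1); violins carry
black per-sample jitter and a red mean ± SD whisker; volcano/MA-style
scatters colour significant genes red and the rest black. Group order
follows the sample sheet, overridable per run.

Every plot script is composed at run time from a central snippet bin:
a master config lists each workflow's steps, a per-step config lists the
snippets (theme, loader, one plot family, saver) in order, and `{{tag}}`
placeholders are substituted from the run context (an unresolved tag is
a build error naming the tag and step). Scripts are standalone Python/
matplotlib, read only their saved data file (exactly the values drawn —
clustering orders and network layouts are precomputed and baked into the
data), and regenerate both PNG and SVG deterministically (fixed
`svg.hashsalt`, no embedded dates, seeded jitter). The pipeline produces
each image *by executing the emitted script*, so re-runnability holds by
construction; a combined per-workflow script carries the shared
theme once, so one edit restyles every plot. Editing a snippet in the
bin changes every future script that uses it.

Reports are single-file HTML (images embedded base64) with a hyperlinked
contents side bar and the description/legend/methods/code of each plot
inside collapsible drop-downs; an index page links the instances.

## Synthetic data generator

The generator emulates the pipeline's full input surface with planted
truth: per-gene base log10 expression ~ N(1.5, 1), per-group shifts
encoding each planted gene's cross-comparison profile (|log2FC| = 2 by
default), iid Gaussian noise (sd 0.25 log10 units), 3 groups × 6
replicates and 2000 genes by default. Differential tables are computed
**from the generated matrix** with a variance-moderated two-group
location test (residual sd pooled across genes — exact under the
generator's homoscedastic noise — then a z-test, BH-adjusted), so
expression and differential files can never contradict each other.
Gene sets draw a configurable fraction (default 0.75) of their members
from planted differential genes; activated (inhibited) regulators point
Activation edges at planted up (down) genes with a configurable
consistency fraction; chromosomes are assigned round-robin unless a
biased chromosome is requested. A truth manifest records every planted
call profile, signature id, enriched set and regulator state.

What it does *not* emulate: count-level noise (negative binomial,
library-size effects), correlated gene modules beyond the planted group
structure, batch effects, or annotation errors. Passing recovery tests
therefore demonstrates correctness of the analysis logic under a clean
generative model, not robustness to real-data pathologies.

Problem sizes in the test and acceptance suites are study-design
choices: calibration checks use 2000 null sets of 300 genes in a
2000-gene universe (large enough that the discrete hypergeometric's
achievable level, ≈ 0.045, sits near nominal); enrichment recovery uses
1000 genes × 6 replicates at default effect strength; recovery checks
that isolate downstream behaviour (profile binning, signature
agglomeration, null fold-change concentration) use 25–30 replicates per
group so that per-gene call error is negligible — at the default noise
sd, fold-change estimation error is replicate-limited, and e.g. mean
|log2FC-hat| on null genes falls below 0.2 only for n ≳ 25 per group.
The demonstration bundle is 800 genes, 3 groups × 3 replicates, 2
comparisons and 4 planted signature profiles, and drives the full
default run (NE + 2 DE + 1 MDE) in a few minutes on one core within
~300 MB.

## Numerical and determinism notes

* All randomness flows through seeded `numpy.random.default_rng`
  generators; two runs with the same inputs and seed produce bitwise
  identical data files, images and manifests.
* p-values are floored at 1e−300 before −log10 for plotting.
* UPGMA min-distance ties resolve deterministically through the linkage
  implementation; random-matrix oracle tests are tie-free by
  construction.
* Degenerate inputs: empty significant-gene lists, zero signatures,
  missing chromosome annotation, fewer than 4 principal components and
  regulator-free networks all render as explicit empty-state plots, so
  a report is always produced and the registry counts are stable.

## Known limitations

* One gene-set database is consumed per run by the DE/MDE plot steps
  (result tables support any number).
* The emitted scripts are Python/matplotlib; the snippet/config
  architecture is plotting-stack agnostic, but no R emitter is shipped.
* Signature discovery is hard assignment; genes are never re-assigned
  after a merge and no significance is attached to signatures
  themselves.
* The shared-genes network uses the smaller node's overlap-gene count as
  the "> 50% shared" denominator; other conventions (union, larger
  node) would give sparser graphs.
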