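# Methods

## Scope and data model

`lncnet` implements the downstream statistics of a two-group (case vs
control) single-channel expression array that profiles lncRNA and mRNA
probes together. The in-memory objects are deliberately plain: an
`ExpressionMatrix` (probes × samples DataFrame, linear positive
intensities or log2, with a sample→group map), a `ProbeAnnotation`
(probe id, molecule type, gene symbol), GMT-backed gene-set databases,
and a `TypedGraph` of lncRNA/mRNA/TF nodes. Loading drops any probe row
with a missing value (with a warning); the analysis never imputes.

## Normalization

Quantile normalization replaces each sample column with the per-rank
across-sample means of the input. Tied values within a column receive
the mean of the rank-means their positions span (the "average ties"
dialect), which makes the transform deterministic and independent of
input row order. Consequences that the tests verify: all columns share
one value multiset, the transform is idempotent, and the grand mean is
conserved exactly (per-rank means redistribute but conserve the total).

Degenerate caveat: on (near-)noiseless data, probes that are constant
across samples can acquire spurious variation after normalization,
because their within-column rank shifts whenever a varying probe crosses
their value. Real arrays are never noiseless; the package's own
zero-noise validation therefore runs on raw log2 intensities, where the
planted structure is exact by construction.

## Differential expression

Testing runs on log2 intensities; fold change is the ratio of
linear-scale group means, reported as a magnitude ≥ 1 plus an up/down
direction (so a 4-fold drop is FC 4.0 "down", matching the reporting
convention of array studies that quote down-regulated FCs above 1).
The default test is the pooled-variance (Student) unpaired t-test — the
classic default of array-analysis suites — with Welch available by flag.
A probe is significant when FC ≥ `fc_min` (default 2.0) and p ≤ `p_max`
(default 0.05), on raw p-values by default; Benjamini–Hochberg adjusted
gating is optional because small-n array screens of this design
traditionally report raw cut-offs. Probes with zero variance in both
groups get p = 1 when the means agree (no evidence) and p = 0 when two
distinct constants are compared.

Top-k selection orders by ascending p, then descending fold change, then
ascending probe id — a total order, so selections are invariant to input
permutation (verified by test). Hierarchical clustering of selected
probes uses average linkage on 1 − Pearson correlation distance;
constant rows get distance 1 to everything (r treated as 0). With three
samples per group, correlation distance displays the group contrast more
directly than Euclidean distance and is insensitive to per-probe scale.

## qPCR concordance

2^−ΔΔCt with the amplification efficiency fixed at 2. ΔCt is computed
per sample and then averaged within groups; for balanced complete tables
this equals the mean-Ct-first order, and it degrades gracefully when a
sample lacks the reference measurement (that sample is dropped with a
warning). Concordance calls a gene "agree" when the array direction and
the side of 1.0 of its relative level coincide; a relative level of
exactly 1 is indeterminate and excluded from the summary fraction.

## Coexpression edges

All lncRNA × mRNA pairs are scored across the pooled samples of both
groups (n = 6 at the default design). Pooling is deliberate: the
group-contrast component of expression is precisely what drives the
biologically interesting lncRNA–mRNA covariation in a case/control
design, and it is what a within-group correlation at n = 3 could never
resolve. Correlations are computed on log2-scale normalized values. The
significance transform is t = r·√((n−2)/(1−r²)) on n−2 degrees of
freedom, two-sided; |r| = 1 maps to p = 0, and constant probes to
(r = 0, p = 1) so they can never form an edge. Retention requires both
|r| ≥ `r_min` (0.7, inclusive, on the magnitude — anticorrelated pairs
become negative edges) and p ≤ `p_max` (0.05); a p-only mode serves the
function-prediction partner sets, which the guilt-by-association recipe
defines by correlation significance alone. Note that at n = 6 the two
gates are genuinely distinct: |r| = 0.7 alone has p ≈ 0.12.

## Enrichment and TF inference

The hypergeometric upper tail P(X ≥ k) for overlap k between a query of
n genes and a set of K genes in a universe of N is evaluated in exact
big-integer arithmetic (one integer tail sum over C(N, n), divided once
with correctly-rounded float division). At the problem sizes of array
analysis this is fast, deterministic across platforms, and bit-equal to
rational enumeration — the package's tests hold it to exact agreement
with an independent `Fraction`-based oracle and to 1e-10 relative
agreement with `scipy.stats.hypergeom.sf`.

The universe defaults to the gene symbols of annotated mRNA probes on
the array, not the whole genome: the array defines what could have been
observed as a coexpression partner. Overlaps are counted on gene
symbols (GMT semantics), with probe→symbol collapsing by set union.
Records are ranked by ascending p, then descending overlap, then set id.
For TF inference, each lncRNA's partner set is scored against every TF
target set and the `top_k` (default 5) lowest-p TFs with nonzero overlap
are retained per lncRNA — "per lncRNA" because the alternative (5 pairs
globally) could not populate the many-TF networks this analysis is meant
to produce. Only the upper tail is computed; depletion is not part of
the procedure.

## Networks

Three builders assemble typed graphs: (1) coexpression edges incident to
the top 100+100 differential lncRNAs, edge type by correlation sign,
weight r; (2) TF→lncRNA edges from the ranked TF pairs, weight p;
(3) a tripartite graph restricted to the top 10+10 lncRNAs with each
lncRNA's `k_mrna` = 2 lowest-p coexpression edges and `k_tf` = 2
lowest-p TFs, so lncRNA degree is bounded by k_mrna + k_tf. Graphs are
simple per edge type; parallel edges of different types are allowed, and
node identity is (id, type) so a TF sharing a symbol with an mRNA stays
distinct. Edge weights preserve the statistic each edge was selected by.
Exports: SIF (edge type as interaction label, isolated nodes as bare
lines), GraphML (via networkx, attributes preserved), and an edge-TSV
that round-trips losslessly (weights written with shortest-round-trip
float repr).

## Synthetic data generator

The generator emulates the statistical structure this analysis assumes,
with defaults at the study design point: n = 3 arrays per group, probe
baselines ~ Normal(8, 1.5) on log2 scale, biological noise 0.25 log2
units, planted fold changes ≥ 2.

log2 intensity = baseline(probe) + group effect + loading·factor(sample)
+ Normal(0, noise_sd), exponentiated to linear scale. The planted group
effect is ±log2(FC) applied to the case group, so the expected
linear-scale group-mean ratio equals the true FC exactly (the log-normal
noise factors are equal in both groups and cancel); at zero noise the
ratio is exact by construction. Each planted module draws one standard
normal factor per sample shared by its probes, giving pairwise
correlation loading²/(loading² + noise_sd²) without specifying a full
covariance matrix — at loading 0.95 and noise 0.2 the population r is
≈ 0.96, and the sample r over 6 arrays clears 0.7 in well over 80% of
replicates. Term and TF-target sets are sampled without replacement from
the mRNA symbol universe; the i-th planted module designates the i-th TF,
whose target set covers ≥ 80% of the module's mRNA symbols, so TF
recovery has a known answer. qPCR tables are generated on the ideal
efficiency model (one fold change = one cycle), reference gene at equal
expected Ct in both groups, so 2^−ΔΔCt recovers planted FCs exactly at
zero noise.

All randomness flows from a single seed through deterministically
spawned sub-streams (one per component), and every writer uses fixed
float formats, so a fixed seed yields byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests
do not establish about real arrays: probe-level spatial artifacts, dye
and batch effects, background correction, intensity-dependent variance
(our noise is homoscedastic on log2 scale), cross-hybridization, or
replicate-spot summarization. Recovery rates measured here are
best-case for data that actually follows the log-normal model.

## Validation problem sizes

The packaged validation runs at sizes chosen to make the statistical
checks sharp while keeping the suite quick: 10,000 probes for null
calibration (3 binomial SEs around 0.05), 200 planted FC=4 probes for
sensitivity, 500 single-pair replicates for coexpression recovery, 100
two-module replicates (400 TF links) for noisy TF recovery, and a
40 × 120-probe pipeline run (twice) for byte-level determinism. The
orchestrated demo scenario uses 300 lncRNA + 800 mRNA probes with 60
planted DE probes and five modules.

## Known limitations

- With n = 3 per group the t-test has 4 degrees of freedom; the screen
  is calibrated but weak for FC < 2 at realistic noise.
- Correlation thresholds at n = 6 retain edges whose individual FDR is
  high; the edge lists are exploratory, as in the original analysis
  style, and no network-wide error control is attempted.
- Guilt-by-association transfers annotation, not mechanism; the TF
  ranking identifies target-set over-representation, not binding.
- The CLI pipeline operates on the bundled synthetic scenario for
  `run-all`; real datasets are analyzed by composing the subcommands
  (`normalize`, `de`, `qpcr`, `coexpress`, `enrich`, `tfnet`, `network`)
  or the library functions on TSV/GMT inputs.
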