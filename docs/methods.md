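# Methods

## Coordinate and counting conventions

All coordinates are 0-based half-open (BED convention) internally; the
GTF-lite gene table (1-based inclusive) is converted on read. Window counts
around a summit are inclusive on both ends, so ±100 bp covers 201 bases.
Overlapping bedGraph records sum: simulated tracks are emitted as fragment
pileups and additivity is the physically sensible composition. Missing
expression p-values default to 1.0 (never significant).

## Differential accessibility ranking

The union of the two conditions' summit calls is, by default, a pure
concatenation (`merge_distance = 0`); when a positive merge distance is given,
nearby same-chromosome summits collapse to the one with the higher local tag
count. Counts in the ±100 bp window are depth-normalised to tags per
10 million before the ratio — the two libraries have no reason to share a
depth — and the fold change uses a pseudocount of 1 (raw-count scale), which
prevents division by zero while barely perturbing realistic peak counts. The
sort on log2 FC is stable with a (chrom, pos) pre-order, so heatmap row order
is reproducible. The classification threshold (default 1.0, i.e. two-fold) is
a free parameter with strict inequalities; a site at exactly ±threshold is
*shared*. Classification is invariant under any depth-normalisation factor
applied equally to both tracks.

## Motif scanning and co-localization

PWM count matrices are smoothed with a pseudo-count (default 0.8, split by the
background composition, default uniform) and scored as log2(p/background) in
bits. Both strands are scanned; per window only the better strand is reported
(ties go to +, which matters for palindromic consensi such as the E-box).
Thresholds are expressed as a fraction of each motif's maximum score (default
0.80) so a single setting behaves comparably across motifs of different
length and information content; an absolute threshold in bits can be given
instead, and a threshold above the maximum yields an empty result with a
warning. `N` bases score as background (0 bits). Composites require a
non-negative inner gap, i.e. overlapping cores never pair.

The bootstrap co-localization statistic is the fraction of the top-ranked
`top_fraction` of union sites whose window (the analysis uses ±100 bp around
the summit, where planted and biological motifs concentrate) contains hits of
both motifs of a pair. The null resamples equally sized site sets from the
full union, by default **without** replacement: at a 10% sampling fraction,
sampling with replacement would create duplicate-site artefacts (a flag
switches this). The empirical p is (1 + #{null ≥ observed}) / (n_boot + 1),
so its floor is 1/(n_boot+1) and a degenerate top fraction of 1.0 gives
exactly 1. Because the statistic is discrete, ties are rounded up: the test
is slightly conservative, and the calibration test in the suite uses a large
top set so the granularity of the statistic stays below the resolution of
the KS uniformity check.

## ChIP integration

Venn sector counts are peak-centric on a declared reference set: peak
boundaries differ per factor, so region merging would change each circle's
total. A merged-region mode (`merged_region_venn`) is emitted alongside for
comparison. The default intersection criterion is ≥1 bp interval overlap; a
summit-distance mode supports sensitivity analysis. The promoter window for
location fractionation is ±2000 bp of the TSS — "promoter" has no canonical
width, so this is an explicit free parameter — and promoter takes precedence
over gene-body containment.

## Expression linkage

"Nearest" is measured from the peak summit to the nearer gene *boundary*, not
the TSS (the side-based 5′/3′ reading of nearest-gene assignment); a TSS mode
is available. A summit inside a gene body links to that gene (the smallest
enclosing span when genes nest); exact distance ties go to the upstream
(lower-coordinate) gene. FPKM ratios use a pseudocount of 0.1 in the
denominator; fold-change boundaries are strict, so a ratio of exactly 4 counts
in neither direction. Rank tables are peak-indexed: a gene linked by several
peaks appears once per peak, flagged. Direction fractions compare mean FPKM
across replicates per condition, with ties reported separately.

## Clustering

Hierarchical clustering runs complete linkage on the Pearson distance
d = 1 − r via scipy; zero-variance rows have no defined correlation and are
flagged with distance 1 to everything. Merge-height ties are resolved by the
linkage backend; on continuous distances the merge sequence is unique, and
the test oracle uses continuous random matrices for exactly that reason.
Clustering input is log2(FPKM + 1).

SOTA grows a binary tree of cells from a single cell at the data mean. Each
cycle splits the leaf with the highest variability (mean Pearson distance of
its members to the cell vector) into two daughters — one inheriting the
mother's vector, the other seeded at the mother's most distant member row —
and trains only those daughters on only the mother's members with
winner-take-most updates (winner 0.1, mother 0.05, losing sister 0.01; rows
presented in seeded random order; at most 30 epochs per cycle or until the
mean distance stabilises within 1e-3). Restricting competition to the split
cell's members keeps settled clusters intact while a mixed cell resolves;
seeding the second daughter from the most distant member peels one coherent
subgroup off instead of bisecting along presentation order. Growth stops when
every leaf's variability is at or below the threshold (default 0.1,
equivalent to a mean within-cell correlation of 0.9), so an infinite
threshold — or a matrix of identical rows — yields a single cluster. The
procedure is deterministic per seed.

## Enrichment

The EASE p-value is the hypergeometric upper tail P(X ≥ k−1) with the
original table margins: decrementing the list-hit count makes a single-gene
overlap score exactly 1 and the statistic conservative relative to the plain
Fisher exact test (an invariant the suite checks, along with an empirical
false-positive rate at or below nominal under random gene lists). No
multiple-testing correction is applied by default, deliberately matching the
raw P < 0.05 reporting convention this pipeline reproduces; a
Benjamini–Hochberg column is available behind a flag. The redundancy filter
is a greedy walk in ascending p that drops any term whose gene-set Jaccard
similarity with an already-kept term exceeds 0.5, truncated to the top 10.

## The synthetic study

Defaults define the study conditions: 2 chromosomes × 200 kb at GC 0.41,
300 regulatory sites (100 A-specific, 100 shared, 100 B-specific) spaced
≥1.2 kb apart, 40 A-specific sites forced co-bound by all three factors
(additional factor memberships join independently with class-dependent
probabilities, never at B-specific sites), 200 genes, and two stages (HB,
HE1) × two conditions × 3 replicates of expression.

Signal is a triangular kernel (half-width 150 bp, apex at the summit) whose
integral is a log-normal site strength (mean 200 tags, σ = 0.5), over uniform
Poisson background (0.005 tags/bp). Condition-specific sites keep
1/enrichment (enrichment = 4) of their mass in the other condition's track,
so the expected window ratio at specific sites equals the enrichment. ChIP
tracks scale the same latent strength per factor (LMO2 1.0, TAL1 0.7,
LDB1 0.5), which makes the strongest peaks of the three factors coincide; in
the knockout genotype LMO2 signal vanishes everywhere and partner signal
survives only at sites that themselves survive. Emitted summit lists are the
planted positions plus a 5% false-positive fraction.

Motif planting writes consensus sequences (recoverable by scanning at the
maximum score): A-specific sites carry an E-box + GATA composite with a
9–10 bp gap on a random strand, B-specific sites a LEF/TCF motif, shared
sites an ETS motif plus SP1 or CREB nearby. The shipped PWMs are synthetic
fixtures built around the canonical cores (CAGCTG, WGATAA, GGAA, CTTTG,
GC-box, TGACGTCA), not measured matrices.

Each co-bound site gets a gene placed 100–250 bp away (or overlapping the
summit in 30% of cases); offsets and lengths (400–600 bp) are bounded so the
linked gene is strictly nearer its own summit than any neighbouring site's
gene at the minimum site spacing — the planted link table is meant to be
geometrically identifiable away from chromosome edges. A few deliberately
short genes (<200 bp) exercise the length filter. Linked genes receive a
planted log2 expression difference (condition A higher) at the late stage,
proportional to site strength (maximum 3), so ChIP signal and expression
effect are monotonically coupled; replicate log2 FPKM adds Gaussian noise
(σ = 0.4) around a log-normal baseline, and p-values come from two-sample
t-tests on the triplets.

The generator also emits a planted three-group profile matrix (50 genes per
group, 6 samples, block profiles of amplitude 2 with noise σ = 0.15) used by
the clustering-recovery checks. The study's own expression tables plant only
up-regulated targets — that keeps the signal-vs-effect correlation
well-posed — and therefore contain two, not three, natural expression
groups; cluster-number discovery is exercised on the profile matrix instead.

What the generator does **not** emulate: mappability and GC bias, fragment-
length structure, read-level noise, peak-width variation between factors,
chromatin-domain (non-nearest) regulation, and replicate-level count
overdispersion beyond the log-normal/Poisson layers. Passing planted-truth
tests therefore demonstrates correctness of the analysis logic under the
stated noise model, not performance on real sequencing data.

## Problem sizes

The default study (400 kb genome, 300 sites, 200 genes, 150-row profile
matrix) generates in about a second and carries every downstream analysis in
a few seconds; oracle-equivalence checks run each core operation against a
brute-force reference on 100+ random small instances (n ≤ 10 sites, 8 genes,
7-row matrices), and null calibrations use 200 bootstrap runs × 199
resamples and 500 random gene lists. These sizes were chosen so the whole
suite exercises every claim in well under typical CI budgets while keeping
all statistical checks adequately powered.
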