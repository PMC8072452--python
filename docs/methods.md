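# Methods

## Model and procedure

The pipeline treats a ChIP-seq experiment as a set of summit-anchored
intervals and an RNA-seq experiment as a per-gene table of log2 fold changes
and BH-adjusted p-values for two contrasts. All coordinates are 0-based,
half-open (BED convention) internally; conversion happens only at the
parse/serialize boundary, and parsers reject out-of-bounds records instead of
clamping.

Distance between a site and a gene is |summit − TSS| on the same chromosome;
cross-chromosome distance is undefined, and sites on chromosomes without
annotated genes are flagged unassigned. Ties (two TSS equidistant from a
summit, or several genes sharing a TSS) break to the lexicographically
smallest gene id, making the assignment deterministic and order-independent.
Distance is strand-agnostic; a signed distance (negative = upstream in gene
orientation) is carried for reporting only. Proximity is inclusive:
distance ≤ threshold (default 1,000 bp) is proximal, so 1,000 → proximal and
1,001 → distal.

The enrichment statistic for a gene cluster at window *w* is the fraction of
cluster genes with at least one summit within *w* (inclusive both sides) of
their TSS. Two nulls are constructed: (i) *random genes* — ten independent
simple random samples of 300 genes drawn without replacement from the
annotated universe, scored on the real site set; (ii) *random sites* — ten
groups of 10,000 positions uniform over the concatenated genome (chromosome
picked proportional to length), each becoming a 400-bp interval clipped to
bounds with the summit at the drawn position, against which the cluster
genes are scored. The Fisher 2×2 table pools the ten groups of a null
(cluster with/without site vs pooled null with/without); pooling uses every
null draw and treats the two null types symmetrically, and per-group
fractions are emitted alongside so either convention can be reproduced. No
correction across clusters × windows is applied to the headline p (raw
Fisher values are reported); `bh_adjust` is available for callers who want
adjusted values.

Coverage comparisons scale every track to reads per 10 million before any
averaging, a single explicit convention that keeps knockout and wild-type
tracks comparable. Profiles average the track's 25-bp bins over
[pos − flank, pos + flank); minus-strand anchors are reversed so downstream
is rightward; windows running off a chromosome end are zero-padded and
flagged per anchor rather than dropped, preserving matrix shape. Region
intensity is the mean over the same window (±2.5 kb by default for the mark
comparison, ±100 bp for co-localization vectors).

## Statistical tests

*Fisher exact* (in-house on `scipy.stats.hypergeom`): two-sided p by the
point-probability rule — the sum of point masses ≤ the observed table's mass
at fixed margins. A relative tie tolerance of 1e-9 is used: large against
floating error in the pmf (~1e-13), but smaller than the gap between any two
*distinct* hypergeometric masses at desk-scale margins (≥ 1/C(n, r)), so
genuine ties are honored and near-ties are not invented. The returned p is
clamped into (0, 1].

*Mann-Whitney U*: midranks for ties. For n₁ + n₂ ≤ 20 the two-sided p is an
exhaustive enumeration over all C(n₁+n₂, n₁) rank assignments, counting those
whose min(U, n₁n₂ − U) is at most the observed one — identical input
multisets therefore give exactly p = 1. Larger samples use the normal
approximation with tie correction and continuity correction
(`scipy.stats.mannwhitneyu`). The enumeration bound is a computational
choice: C(20, 10) assignments evaluate in well under a second, while exact
enumeration at the 300-site scale of the pipeline is infeasible and
unnecessary.

*Spearman*: Pearson correlation of midranks. A constant vector has no rank
ordering; its correlation is defined as 0 with a warning (rather than NaN)
so the co-localization matrix stays total. Cross-checked in tests against
`scipy.stats.spearmanr`.

*BH adjustment* delegates to `statsmodels.stats.multitest.multipletests`
(method `fdr_bh`) behind input validation; tests verify it against an
explicit min-over-suffix step-up oracle to 1e-12.

## Cluster-pattern convention

Two facts anchor the cluster scheme: clusters I–III are the upregulated
patterns and cluster V is "down in pre-B only". The remaining numeral
mapping (II vs III, IV vs VI) follows heatmap-ordering convention —
II = up/ns, III = ns/up, IV = down/down, VI = ns/down — and is a convention,
not a derived fact. Genes significant in both contrasts with opposite signs
are *discordant*: they belong to no cluster, are labelled `none`, and are
counted separately, so cluster counts plus the discordant count equal the
significant-gene count.

## Synthetic data: what it emulates, and what it does not

The generator plants the statistical structure the pipeline is meant to
detect, with one master seed fanned out to fixed, named child streams per
artifact (annotation = 1, peaks = 2, DE table = 3, coverage = 10–13), so a
single artifact can be regenerated alone and identical (seed, config) gives
byte-identical serialized outputs.

Defaults are the study-scale conditions: a 20 × 125 Mb genome (mm9 total
length, so that accidental proximity of uniformly placed sites stays ~2%),
24,421 genes with uniform TSS and fair-coin strands, 13,163 sites of which a
Bernoulli-0.74 fraction have their summit placed uniformly within ±1 kb of a
random TSS (the rest uniform over the genome; intervals are fixed 400-bp,
summit-centered, clipped to bounds), and a DE table of 916 cluster genes
split {I: 150, II: 100, III: 100, IV: 120, V: 300, VI: 146} — the total is
the printed study count; the per-cluster split is a one-time choice with V
matching the 300-gene null group size. Planted cluster genes draw
significant-contrast values as |log2FC| ~ U(log2 1.5, 3) with FDR ~
log-uniform(1e-8, 0.01); everything else draws log2FC ~ N(0, 0.2²) with FDR
~ U(0.05, 1), so the inclusive thresholds recover the planted labels
exactly.

Association planting: for cluster *c* with probability *p*, each member is
drawn from the pool of peak-proximal genes with probability *p* (without
replacement), else from the non-proximal pool; *p* = None means a uniform
draw from the whole universe — the same process as the random-gene null,
which is the honest no-association control used for type-I calibration.
Defaults plant association only at the downregulated clusters
(IV = VI = 0.5, V = 0.6; I–III uniform): at the study-scale empirical
background (~0.33 of genes have a site within 1 kb) a planted 0.4 would be
statistically invisible at these cluster sizes, while the emulated structure
is a strong overrepresentation at the downregulated clusters, strongest in
V.

Coverage is per-bin Poisson with rate bg_rate (2 reads / 25-bp bin) plus a
Gaussian bump (sd 150 bp, evaluated within ±5 sd) at every factor summit.
The amplitude averages bg_rate × (peak_fold − 1) (peak_fold default 6) and
scales with each site's peak score: sites carry heterogeneous, track-shared
strengths, which is what makes replicate-track rank concordance (Spearman ~
0.95 at the demo scale) measurable at all — with identical amplitudes the
per-site variation would be pure Poisson noise. For the (KO, histone_mark)
track every amplitude is multiplied by ko_mark_fold (default 2.0 — the mark
gain at binding sites when the eraser is lost has no printed effect size and
is a free simulation parameter). The factor's own enrichment is kept equal
in both conditions; the condition label affects only the mark.

Not emulated: read-level data (FASTQ, fragment lengths, mappability),
replicate count dispersion (adjusted p-values are planted, not fitted from
negative-binomial counts), non-uniform gene/TSS density, chromatin-domain
structure, and input/IP-efficiency differences. Passing tests therefore
demonstrate that the statistics recover planted structure of realistic
shape and scale, not that they are robust to every artifact of real
sequencing data.

## Problem sizes

Annotation-level stages (nearest-TSS, clusters, enrichment) run at full
study scale — 24,421 genes, 13,163 sites, ten 300-gene and ten
10,000-location null groups on the 2.5-Gb genome — in ~2 s. Coverage-bearing
stages use a documented demo preset (2 × 2.5 Mb, 600 genes, 300 sites,
25-bp bins): whole-genome binned tracks at mm9 scale would be
100M-bin arrays with nothing to teach beyond what the 300-site scale already
shows, so the demo preset is the package's chosen scale for profile, mark
comparison, and co-localization analyses. Replicated calibrations (100
seeded replicates each) use a 2 × 30 Mb / 3,000-gene configuration with 745
sites placed so that the empirical 1-kb background is ~0.2, matching the
planted-V-0.6-vs-0.2 design of the power checks.

## Numerical and degenerate-input choices

- bedGraph rebinning is length-weighted averaging over each bin's actual
  base span (the final bin of a chromosome may be truncated), so constant
  tracks stay constant; uncovered bases count as zero; overlapping records
  are a format error.
- Profile windows align anchors to the track's bin grid by floor division;
  sub-bin anchor offsets (< 25 bp) are not interpolated.
- narrowPeak summit = start + column-10 offset, with offset −1 falling back
  to the BED midpoint rule floor((start+end)/2).
- Peak-set overlap is ≥ 1 bp interval overlap; because overlap is
  many-to-many, Venn counts are reported from both anchorings. Union merging
  keeps the summit/score of the highest-scoring member; intersection mode
  keeps intervals of the first set that overlap every other set.
- The union/merge and window queries are deterministic under stable sorts;
  distance ranking is a stable (mergesort) ascending sort, ties keeping
  input order.
- Empty clusters, empty groups, all-zero Fisher tables, zero library sizes,
  and unsorted window lists are validation errors, not silent results.

## Known limitations

- The Fisher table construction (pooled nulls) is one defensible choice; the
  per-group fractions are emitted so per-group testing can be reproduced,
  but the headline p would differ under that convention.
- `run_all` drives the synthetic demo end to end; on external data the
  stages are run individually (CLI subcommands or library calls), since a
  real dataset arrives with its own upstream peak calling and DE fitting.
- Random null sites are fixed-width (the generator's 400-bp site width), not
  width-matched to the observed peak-width distribution; with summit-based
  window queries the width only affects interval overlap reporting, not
  proximity fractions.
- bigWig input is not implemented; bedGraph is the coverage dialect (the
  `CoverageTrack` contract would admit a bigWig reader without API change).
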