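# chipde

Integration of ChIP-seq binding sites with RNA-seq differential expression,
built around the question a chromatin-factor knockout study has to answer:
*are the genes that change expression when the factor is lost the same genes
the factor binds?*  The motivating setting is a B-cell-precursor knockout of
a deubiquitinase that removes the repressive histone mark H2AK119ub, but
every stage operates on standard formats (BED/narrowPeak, bedGraph, TSV) and
applies to any peak set, coverage track, and two-contrast DE table.

The package is organised as an analysis project: the computation lives in
`src/chipde/`, numbered drivers under `analysis/` run the stages in order and
write tables under `results/`, and a synthetic-data generator with planted,
parameterised structure provides ground truth for every statistic.

## What it computes

**Peak-to-TSS annotation.** Each binding site is anchored at its summit and
assigned the gene minimising |summit − TSS| on the same chromosome; sites
are classified *gene-proximal* (distance ≤ 1 kb, inclusive) or *gene-distal*
and ranked by distance.

**Expression clusters.** Genes pass the expression filter (CPM ≥ 5 in ≥ 3
samples), are called significant per contrast at |FC| ≥ 1.5 and
Benjamini–Hochberg FDR ≤ 0.01 (both inclusive), and grouped into six
clusters by their up/down pattern across the pre-B and immature-B contrasts
(I = up/up, II = up/ns, III = ns/up, IV = down/down, V = down/ns,
VI = ns/down).

**Enrichment vs resampled nulls.** For a cluster *C* and TSS window *w*, the
statistic is the fraction of *C* with ≥ 1 summit within *w* of the TSS. It is
compared against ten random groups of 300 genes (on the real sites) and ten
random groups of 10,000 genomic locations (for the cluster genes) by a
two-sided Fisher exact test on the pooled 2×2 table,

```
            with site   without
cluster         a          b
pooled null     c          d
```

with the two-sided p computed by the point-probability rule
(Σ of hypergeometric point masses ≤ that of the observed table).

**Signal profiles and the knockout comparison.** Tracks are scaled to reads
per 10 million, averaged in 25-bp bins over ±flank windows around summits,
and per-site ±2.5 kb mark intensities are compared between knockout and wild
type with the two-sided Mann–Whitney U test.  Cross-dataset concordance is
the pairwise Spearman ρ of per-site densities ±100 bp around summits.

## Worked example

```sh
python analysis/01_simulate.py
python analysis/02_annotate_peaks.py
python analysis/03_expression_clusters.py
python analysis/04_signal_profiles.py
python analysis/05_colocalization.py
python analysis/06_enrichment.py
```

The simulation plants an mm9-scale genome (20 × 125 Mb) with 24,421 genes,
13,163 binding sites of which 74% are placed within 1 kb of a TSS, and a
916-gene DE table whose downregulated clusters preferentially sit at
peak-proximal genes. The drivers then print, among others:

```
13163 sites: 9763 gene-proximal (<=1 kb), 3400 gene-distal (74.2% proximal)
916 significant genes (0 discordant, excluded from clusters)
mark intensity KO vs WT at 300 sites: median 83.47 vs 68.17, Mann-Whitney p = 4.67e-15
fraction of cluster genes with a site within 1 kb of the TSS:
  V:  64.7%  (random genes 35.5%, Fisher p = 2.8e-22)
```

Reading: the nearest-TSS classification recovers the planted 74% proximal
share; the significance rule recovers all 916 planted cluster genes; the
knockout's doubled repressive-mark amplitude at binding sites is detected by
the rank test; and cluster V — planted with 0.6 association against a ~0.33
genome-wide background — is the strongly enriched cluster, exactly the
structure the generator encodes.

The same stages are exposed as a CLI (`chipde simulate|prep-expression|
annotate|profile|colocalize|enrich|run-all`) for running on external data;
`chipde run-all --seed N --outdir DIR` reproduces a full demo run
byte-identically for a fixed seed.

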