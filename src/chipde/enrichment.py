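"""Cluster-vs-binding-site enrichment against resampled genomic nulls.

For each differential-expression cluster and each TSS window, the statistic
is the fraction of cluster genes with at least one binding-site summit
within the window of their TSS.  It is compared against two constructed
nulls, mirroring the study design:

* random genes — ten groups of genes sampled uniformly without replacement
  from the annotated universe, scored against the real peak set;
* random binding sites — ten groups of uniform genomic locations (chromosome
  chosen proportional to length), against which the cluster genes are scored.

Each comparison is a two-sided Fisher exact test on the 2x2 table of
[cluster: with/without site] vs [pooled null groups: with/without site]
(per-group tables are also emitted; pooling uses every null draw and treats
both null types symmetrically).  The two-sided p follows the
point-probability rule: the sum of hypergeometric probabilities of all
tables, at fixed margins, no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SizingError, ValidationError
from .genome_io import GenomeAnnotation, PeakSet
from .peak_annotation import genes_with_site_within


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of nonnegative integers.

    Sums hypergeometric point probabilities <= that of the observed table
    (with a small relative tolerance against floating-point ties).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any():
        raise ValidationError("table entries must be nonnegative")
    n = int(t.sum())
    if n == 0:
        raise ValidationError("all-zero table")
    row1 = int(t[0].sum())
    col1 = int(t[:, 0].sum())
    support_lo = max(0, row1 + col1 - n)
    support_hi = min(row1, col1)
    k = np.arange(support_lo, support_hi + 1)
    pmf = stats.hypergeom.pmf(k, n, row1, col1)
    p_obs = stats.hypergeom.pmf(int(t[0, 0]), n, row1, col1)
    # 1e-9 relative slack: generous against pmf floating error, but smaller
    # than the gap between any two distinct hypergeometric point masses at
    # desk-scale margins, so ties are honored and near-ties are not invented
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(max(p, np.finfo(float).tiny), 1.0)


def random_gene_clusters(
    universe, n_groups: int = 10, group_size: int = 300, seed: int | None = 0
) -> list[set[str]]:
    """Ten (by default) simple random gene samples, drawn independently."""
    pool = np.array(sorted(universe))
    if group_size > pool.size:
        raise SizingError(f"universe of {pool.size} genes < group size {group_size}")
    if n_groups < 1 or group_size < 1:
        raise ValidationError("n_groups and group_size must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        set(rng.choice(pool, size=group_size, replace=False)) for _ in range(n_groups)
    ]


def random_binding_sites(
    chrom_sizes: dict[str, int],
    n_groups: int = 10,
    group_size: int = 10_000,
    site_width: int = 400,
    seed: int | None = 0,
) -> list[PeakSet]:
    """Ten groups of uniform genomic locations as null binding sites.

    Positions are uniform over the concatenated genome (so each chromosome is
    chosen proportional to its length); each becomes an interval of
    ``site_width`` centered on the position, clipped to bounds, with the
    summit at the drawn position.
    """
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    if total <= 0:
        raise ValidationError("genome length must be positive")
    if site_width < 1:
        raise ValidationError("site_width must be >= 1")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    rng = np.random.default_rng(seed)
    half = site_width // 2
    out = []
    for g in range(n_groups):
        pos = np.sort(rng.integers(0, total, size=group_size))
        idx = np.searchsorted(offsets, pos, side="right") - 1
        local = pos - offsets[idx]
        rows = []
        for j in range(group_size):
            chrom = chroms[idx[j]]
            summit = int(local[j])
            L = chrom_sizes[chrom]
            start = max(summit - half, 0)
            end = min(summit + half, L)
            summit = min(max(summit, start), end - 1)
            rows.append((chrom, start, end, f"rand{g}_{j}", 0.0, summit))
        out.append(
            PeakSet(
                name=f"random_sites_{g}",
                peaks=pd.DataFrame(
                    rows, columns=["chrom", "start", "end", "name", "score", "summit"]
                ),
            )
        )
    return out


@dataclass
class EnrichmentReport:
    """Per-(cluster, window) fractions with null comparisons and Fisher p's."""

    cluster: str
    table: pd.DataFrame
    # columns: window_bp, n_genes, n_with_site, fraction,
    #          null_gene_fractions (list), null_site_fractions (list),
    #          null_gene_mean, null_site_mean,
    #          fisher_p_vs_random_genes, fisher_p_vs_random_sites

    def row(self, window: int) -> pd.Series:
        hit = self.table[self.table["window_bp"] == window]
        if hit.empty:
            raise ValidationError(f"window {window} not in report")
        return hit.iloc[0]


def cluster_enrichment(
    cluster_genes,
    annotation: GenomeAnnotation,
    peaks: PeakSet,
    windows,
    null_gene_groups: list[set[str]],
    null_site_sets: list[PeakSet],
    cluster_label: str = "",
) -> EnrichmentReport:
    """Windowed peak-proximity fractions for a gene cluster vs both nulls.

    For each window w: the cluster fraction uses the real peak set; the
    random-gene null scores each null gene group on the real peaks; the
    random-site null scores the cluster genes on each random site group.
    Fisher tables pool the ten null groups.
    """
    cluster_genes = set(cluster_genes)
    if not cluster_genes:
        raise ValidationError("empty cluster")
    universe = set(annotation.gene_ids())
    if not cluster_genes <= universe:
        raise ValidationError("cluster genes must be annotated")
    windows = list(windows)
    if windows != sorted(windows):
        raise ValidationError("windows must be sorted ascending")

    rows = []
    for w in windows:
        with_site = genes_with_site_within(annotation, peaks, w)
        n_genes = len(cluster_genes)
        n_with = len(cluster_genes & with_site)

        gene_fracs = [len(g & with_site) / len(g) for g in null_gene_groups]
        gene_with = sum(len(g & with_site) for g in null_gene_groups)
        gene_total = sum(len(g) for g in null_gene_groups)

        site_hits = [
            len(cluster_genes & genes_with_site_within(annotation, rs, w))
            for rs in null_site_sets
        ]
        site_fracs = [h / n_genes for h in site_hits]
        site_with = sum(site_hits)
        site_total = n_genes * len(null_site_sets)

        p_genes = fisher_exact(
            [[n_with, n_genes - n_with], [gene_with, gene_total - gene_with]]
        ) if null_gene_groups else float("nan")
        p_sites = fisher_exact(
            [[n_with, n_genes - n_with], [site_with, site_total - site_with]]
        ) if null_site_sets else float("nan")

        rows.append(
            {
                "window_bp": int(w),
                "n_genes": n_genes,
                "n_with_site": n_with,
                "fraction": n_with / n_genes,
                "null_gene_fractions": gene_fracs,
                "null_site_fractions": site_fracs,
                "null_gene_mean": float(np.mean(gene_fracs)) if gene_fracs else float("nan"),
                "null_site_mean": float(np.mean(site_fracs)) if site_fracs else float("nan"),
                "fisher_p_vs_random_genes": p_genes,
                "fisher_p_vs_random_sites": p_sites,
            }
        )
    return EnrichmentReport(cluster=cluster_label, table=pd.DataFrame(rows))
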