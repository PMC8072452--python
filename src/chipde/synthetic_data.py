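"""Synthetic genomes with planted, parameterized regulatory structure.

Every downstream stage of the pipeline is exercised against data whose truth
is known by construction:

* a gene universe with uniformly placed TSS on a multi-chromosome genome;
* a binding-site set in which a planted fraction of summits falls within a
  chosen distance of a randomly picked TSS (the rest are uniform over the
  genome), emulating a mostly promoter-proximal transcription-factor peak set;
* Poisson-background coverage tracks with Gaussian-shaped (sd 150 bp)
  enrichment at factor summits, where the repressive histone mark gains a
  configurable fold at factor sites in the knockout condition;
* a differential-expression table whose planted clusters follow the six
  up/down patterns across the two contrasts, with cluster membership drawn
  preferentially from peak-proximal genes at a per-cluster association
  probability.

Reproducibility contract: one master seed, fanned out to fixed named child
streams per artifact, so identical ``(seed, config)`` reproduces byte-identical
serialized outputs and any single artifact can be regenerated alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import peak_annotation
from .errors import SizingError, ValidationError
from .genome_io import (
    CLUSTER_LABELS,
    CoverageTrack,
    DETable,
    GenomeAnnotation,
    PeakSet,
    n_bins,
)

# fixed per-artifact child-stream tags (order is part of the contract)
_STREAMS = {
    "annotation": 1,
    "peaks": 2,
    "de_table": 3,
    ("WT", "factor"): 10,
    ("WT", "histone_mark"): 11,
    ("KO", "factor"): 12,
    ("KO", "histone_mark"): 13,
}

CONDITIONS = ("WT", "KO")
MARKS = ("factor", "histone_mark")

PEAK_WIDTH = 400          # fixed interval width centered near the summit
ENRICH_SD = 150.0         # Gaussian enrichment kernel sd, bp
ENRICH_SPAN_SD = 5.0      # kernel evaluated within +- this many sd of a summit

# cluster expression patterns across the (preB, immB) contrasts
CLUSTER_PATTERNS = {
    "I": ("up", "up"),
    "II": ("up", "ns"),
    "III": ("ns", "up"),
    "IV": ("down", "down"),
    "V": ("down", "ns"),
    "VI": ("ns", "down"),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted structure.

    ``association_prob`` maps a cluster label to the probability that one of
    its genes is drawn from the peak-proximal gene pool; ``None`` for a label
    means its genes are drawn uniformly from the universe (the same process
    as the random-gene null — the honest no-association control).  Labels
    absent from the mapping fall back to ``background_assoc_prob``.
    """

    seed: int = 0
    n_chroms: int = 20
    chrom_length: int = 125_000_000
    n_genes: int = 24_421
    n_peaks: int = 13_163
    proximal_fraction: float = 0.74
    proximal_threshold: int = 1000
    cluster_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 150, "II": 100, "III": 100, "IV": 120, "V": 300, "VI": 146}
    )
    association_prob: dict[str, float | None] = field(
        default_factory=lambda: {
            # upregulated clusters sit at the universe background (uniform
            # draw); binding-site overrepresentation is planted only for the
            # downregulated clusters, strongest in V
            "I": None, "II": None, "III": None,
            "IV": 0.5, "V": 0.6, "VI": 0.5,
        }
    )
    background_assoc_prob: float = 0.2
    bg_rate: float = 2.0
    peak_fold: float = 6.0
    ko_mark_fold: float = 2.0
    bin_size: int = 25
    libsize: int = 10_000_000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise SizingError("n_genes must be >= 1")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise SizingError("need at least one chromosome of positive length")
        if self.n_peaks < 0:
            raise ValidationError("n_peaks must be >= 0")
        for name in ("proximal_fraction", "background_assoc_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for label, p in self.association_prob.items():
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValidationError(f"association_prob[{label}] must be in [0, 1]")
        if any(n < 0 for n in self.cluster_sizes.values()):
            raise ValidationError("cluster sizes must be >= 0")
        if sum(self.cluster_sizes.values()) > self.n_genes:
            raise SizingError("cluster sizes sum exceeds n_genes")
        if self.bg_rate < 0:
            raise ValidationError("bg_rate must be >= 0")
        if self.peak_fold < 1:
            raise ValidationError("peak_fold must be >= 1")
        if self.ko_mark_fold < 1:
            raise ValidationError("ko_mark_fold must be >= 1")
        if self.proximal_threshold < 0 or self.bin_size < 1 or self.libsize < 1:
            raise ValidationError("threshold/bin_size/libsize out of range")
        # genes are placed uniformly; demand some elbow room per gene
        if self.n_chroms * self.chrom_length < 10 * self.n_genes:
            raise SizingError("genome too small for requested gene density")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def rng(self, stream: str | tuple[str, str]) -> np.random.Generator:
        tag = _STREAMS[stream]
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), tag]))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=int(seed))


def demo_config(seed: int = 0) -> SyntheticConfig:
    """Desk-scale preset for coverage-bearing stages and end-to-end demos.

    Two 2.5 Mb chromosomes, 600 genes and 300 sites: small enough that whole
    tracks are generated in milliseconds, while keeping the planted structure
    (proximal fraction, cluster association, knockout mark gain) intact.
    """
    return SyntheticConfig(
        seed=seed,
        n_chroms=2,
        chrom_length=2_500_000,
        n_genes=600,
        n_peaks=300,
        cluster_sizes={"I": 30, "II": 20, "III": 20, "IV": 25, "V": 60, "VI": 25},
        association_prob={"I": None, "II": None, "III": None,
                          "IV": 0.5, "V": 0.6, "VI": 0.5},
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_annotation(config: SyntheticConfig) -> GenomeAnnotation:
    """Gene universe with uniform TSS placement and fair-coin strands."""
    rng = config.rng("annotation")
    sizes = config.chrom_sizes
    chrom_names = list(sizes)
    chrom_idx = rng.integers(0, config.n_chroms, size=config.n_genes)
    tss = rng.integers(0, config.chrom_length, size=config.n_genes)
    strand = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    width = len(str(config.n_genes))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:0{width}d}" for i in range(config.n_genes)],
            "chrom": [chrom_names[i] for i in chrom_idx],
            "strand": strand,
            "tss": tss,
        }
    )
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def generate_peaks(config: SyntheticConfig, annotation: GenomeAnnotation) -> PeakSet:
    """Binding sites: a planted fraction summit-anchored near random TSS.

    Each peak is an independent Bernoulli(``proximal_fraction``) draw: planted
    peaks put their summit uniformly within ±``proximal_threshold`` of a
    randomly chosen TSS, the rest land uniformly on the genome.  Intervals are
    fixed-width (400 bp) centered on the summit, clipped to chromosome bounds.
    """
    if len(annotation) == 0:
        raise ValidationError("annotation must be nonempty")
    rng = config.rng("peaks")
    sizes = config.chrom_sizes
    chrom_names = list(sizes)
    half = PEAK_WIDTH // 2

    n = config.n_peaks
    is_planted = rng.random(n) < config.proximal_fraction
    gene_pick = rng.integers(0, len(annotation), size=n)
    offsets = rng.integers(-config.proximal_threshold, config.proximal_threshold + 1, size=n)
    uniform_chrom = rng.integers(0, config.n_chroms, size=n)
    uniform_pos = rng.integers(0, config.chrom_length, size=n)
    scores = np.round(rng.uniform(5.0, 100.0, size=n), 4)

    gene_chrom = annotation.genes["chrom"].to_numpy()
    gene_tss = annotation.genes["tss"].to_numpy()

    records = []
    width = len(str(max(n, 1)))
    for i in range(n):
        if is_planted[i]:
            chrom = gene_chrom[gene_pick[i]]
            summit = int(gene_tss[gene_pick[i]]) + int(offsets[i])
        else:
            chrom = chrom_names[uniform_chrom[i]]
            summit = int(uniform_pos[i])
        L = sizes[chrom]
        summit = min(max(summit, 0), L - 1)
        start = max(summit - half, 0)
        end = min(summit + half, L)
        records.append((chrom, start, end, f"peak_{i:0{width}d}", float(scores[i]), summit))
    peaks = pd.DataFrame(
        records, columns=["chrom", "start", "end", "name", "score", "summit"]
    )
    return PeakSet(name="synthetic_factor", peaks=peaks)


def generate_coverage(
    config: SyntheticConfig,
    peaks: PeakSet,
    condition: str = "WT",
    mark: str = "factor",
) -> CoverageTrack:
    """Binned read counts: Poisson background + Gaussian summit enrichment.

    Per-bin counts are Poisson with rate ``bg_rate`` plus, around every factor
    summit, a Gaussian bump (sd 150 bp) whose amplitude averages
    ``bg_rate*(peak_fold-1)`` and scales with the site's peak score, so sites
    carry heterogeneous but track-shared strengths (as real binding sites do —
    this is what makes cross-dataset rank concordance measurable).  For the
    (KO, histone_mark) track every amplitude is further multiplied by
    ``ko_mark_fold``, modelling the repressive-mark gain when the eraser is
    lost.  Each (condition, mark) pair has its own child random stream.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}")
    if mark not in MARKS:
        raise ValidationError(f"mark must be one of {MARKS}")
    peaks.validate_bounds(config.chrom_sizes)
    rng = config.rng((condition, mark))
    sizes = config.chrom_sizes
    bs = config.bin_size

    amplitude = config.bg_rate * (config.peak_fold - 1.0)
    if condition == "KO" and mark == "histone_mark":
        amplitude *= config.ko_mark_fold

    span_bins = int(math.ceil(ENRICH_SPAN_SD * ENRICH_SD / bs))
    values: dict[str, np.ndarray] = {}
    total = 0
    for chrom, length in sizes.items():
        nb = n_bins(length, bs)
        rate = np.full(nb, config.bg_rate, dtype=float)
        if amplitude > 0:
            sub = peaks.peaks.loc[peaks.peaks["chrom"] == chrom]
            summits = sub["summit"].to_numpy()
            scores = sub["score"].to_numpy(dtype=float)
            mean_score = float(peaks.peaks["score"].mean()) or 1.0
            for summit, score in zip(summits, scores):
                site_amp = amplitude * (score / mean_score if mean_score > 0 else 1.0)
                c = int(summit) // bs
                lo = max(c - span_bins, 0)
                hi = min(c + span_bins + 1, nb)
                centers = (np.arange(lo, hi) + 0.5) * bs
                rate[lo:hi] += site_amp * np.exp(
                    -0.5 * ((centers - summit) / ENRICH_SD) ** 2
                )
        counts = rng.poisson(rate).astype(float)
        total += int(counts.sum())
        values[chrom] = counts
    return CoverageTrack(
        name=f"{condition}_{mark}",
        bin_size=bs,
        values=values,
        libsize=max(total, 1),
        chrom_sizes=sizes,
    )


def generate_de_table(
    config: SyntheticConfig, annotation: GenomeAnnotation, peaks: PeakSet
) -> DETable:
    """DE table with planted cluster patterns and peak-proximal association.

    Cluster genes get log2 fold changes of the correct sign with magnitude at
    least log2(1.5) and adjusted p <= 0.01 on their significant contrasts;
    everything else draws null fold changes with adjusted p above threshold.
    For a cluster with association probability p, each member is taken from
    the pool of genes having a summit within ``proximal_threshold`` of their
    TSS with probability p (without replacement), otherwise from the
    non-proximal pool; ``None`` means a uniform draw from the whole universe.
    """
    rng = config.rng("de_table")
    gene_ids = np.array(annotation.gene_ids())
    proximal = peak_annotation.genes_with_site_within(
        annotation, peaks, config.proximal_threshold
    )
    is_prox = np.isin(gene_ids, list(proximal))

    available = set(range(len(gene_ids)))
    prox_pool = [i for i in range(len(gene_ids)) if is_prox[i]]
    dist_pool = [i for i in range(len(gene_ids)) if not is_prox[i]]
    rng.shuffle(prox_pool)
    rng.shuffle(dist_pool)

    def take(pool: list[int]) -> int:
        while pool:
            i = pool.pop()
            if i in available:
                available.discard(i)
                return i
        raise SizingError("gene pool exhausted for requested cluster sizes")

    assignment: dict[int, str] = {}
    for label in CLUSTER_LABELS:
        size = config.cluster_sizes.get(label, 0)
        if size == 0:
            continue
        p = config.association_prob.get(label, config.background_assoc_prob)
        for _ in range(size):
            if p is None:
                # uniform over what remains of the universe: same process as
                # the random-gene null groups
                pool = prox_pool if rng.random() < len(prox_pool) / max(
                    len(prox_pool) + len(dist_pool), 1
                ) else dist_pool
                idx = take(pool if pool else (dist_pool or prox_pool))
            else:
                want_prox = rng.random() < p
                pool = prox_pool if want_prox else dist_pool
                if not pool:
                    raise SizingError(
                        f"not enough {'proximal' if want_prox else 'distal'} genes "
                        f"for cluster {label}"
                    )
                idx = take(pool)
            assignment[idx] = label

    n = len(gene_ids)
    log2fc = {c: rng.normal(0.0, 0.2, size=n) for c in ("preB", "immB")}
    fdr = {c: rng.uniform(0.05, 1.0, size=n) for c in ("preB", "immB")}
    sig_mag = {c: rng.uniform(math.log2(1.5), 3.0, size=n) for c in ("preB", "immB")}
    sig_fdr = {c: 10.0 ** rng.uniform(-8.0, math.log10(0.01), size=n) for c in ("preB", "immB")}

    cluster_col = np.full(n, "none", dtype=object)
    for idx, label in assignment.items():
        cluster_col[idx] = label
        for contrast, direction in zip(("preB", "immB"), CLUSTER_PATTERNS[label]):
            if direction == "ns":
                continue
            sign = 1.0 if direction == "up" else -1.0
            log2fc[contrast][idx] = sign * sig_mag[contrast][idx]
            fdr[contrast][idx] = sig_fdr[contrast][idx]

    rows = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc_preB": log2fc["preB"],
            "fdr_preB": fdr["preB"],
            "log2fc_immB": log2fc["immB"],
            "fdr_immB": fdr["immB"],
            "cluster": cluster_col,
        }
    )
    return DETable(rows=rows)
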