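"""Expression filtering, significance calls, and cluster-pattern assignment.

The RNA-seq side of the pipeline: counts-per-million normalization, the
"CPM >= 5 in at least 3 samples" expressed-gene filter, Benjamini-Hochberg
adjustment, and the fold-change/FDR significance rule (|FC| >= 1.5,
BH-adjusted p <= 0.01, both thresholds inclusive).  Significant genes are
grouped into the six expression-pattern clusters across the pre-B and
immature-B contrasts:

=======  ==========  ==========
cluster  pre-B       immature B
=======  ==========  ==========
I        up          up
II       up          ns
III      ns          up
IV       down        down
V        down        ns
VI       ns          down
=======  ==========  ==========

Genes up in one contrast and down in the other are discordant: they receive
the label ``none`` and are counted separately (the cluster scheme has no
place for them).  Upstream normalization (TMM, quantile) is accepted as
given; this module consumes raw counts or a prepared DE table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .genome_io import CLUSTER_LABELS, DETable


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples; library size = column sum."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``counts[g, s] * 1e6 / libsize[s]``."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValidationError(f"zero library size in sample {bad!r}")
    return counts.counts * 1e6 / lib


def filter_expressed(
    counts: CountMatrix, min_cpm: float = 5.0, min_samples: int = 3
) -> set[str]:
    """Genes with CPM >= ``min_cpm`` (inclusive) in >= ``min_samples`` samples."""
    if min_cpm < 0 or min_samples < 0:
        raise ValidationError("thresholds must be >= 0")
    c = cpm(counts)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    return set(c.index[keep])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_significant(
    log2fc: float,
    fdr: float,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.01,
) -> str:
    """'up', 'down', or 'ns' at inclusive |FC| and FDR thresholds."""
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must be > 1")
    cut = math.log2(fc_threshold)
    if fdr <= fdr_threshold:
        if log2fc >= cut:
            return "up"
        if log2fc <= -cut:
            return "down"
    return "ns"


def _classify_columns(
    de: pd.DataFrame, contrast: str, fc_threshold: float, fdr_threshold: float
) -> np.ndarray:
    cut = math.log2(fc_threshold)
    fc = de[f"log2fc_{contrast}"].to_numpy(dtype=float)
    q = de[f"fdr_{contrast}"].to_numpy(dtype=float)
    out = np.full(len(de), "ns", dtype=object)
    sig = q <= fdr_threshold
    out[sig & (fc >= cut)] = "up"
    out[sig & (fc <= -cut)] = "down"
    return out


_PATTERN_TO_CLUSTER = {
    ("up", "up"): "I",
    ("up", "ns"): "II",
    ("ns", "up"): "III",
    ("down", "down"): "IV",
    ("down", "ns"): "V",
    ("ns", "down"): "VI",
}


@dataclass(frozen=True)
class ClusterAssignment:
    table: DETable
    counts: dict[str, int]       # per-cluster gene counts
    n_discordant: int            # up in one contrast, down in the other

    @property
    def n_significant(self) -> int:
        return sum(self.counts.values()) + self.n_discordant


def assign_clusters(
    de: DETable, fc_threshold: float = 1.5, fdr_threshold: float = 0.01
) -> ClusterAssignment:
    """Assign each gene its expression-pattern cluster (or 'none').

    Every gene significant in at least one contrast lands in exactly one
    cluster or the discordant bucket; cluster counts therefore sum to the
    significant-gene count minus the discordant count.
    """
    rows = de.rows.copy()
    calls = {
        c: _classify_columns(rows, c, fc_threshold, fdr_threshold)
        for c in ("preB", "immB")
    }
    labels = np.full(len(rows), "none", dtype=object)
    discordant = 0
    for i, pattern in enumerate(zip(calls["preB"], calls["immB"])):
        label = _PATTERN_TO_CLUSTER.get(pattern)
        if label is not None:
            labels[i] = label
        elif pattern != ("ns", "ns"):
            discordant += 1
    rows["cluster"] = labels
    counts = {lab: int((labels == lab).sum()) for lab in CLUSTER_LABELS}
    return ClusterAssignment(table=DETable(rows=rows), counts=counts, n_discordant=discordant)
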