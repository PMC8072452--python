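"""Cross-dataset binding concordance.

Given several ChIP datasets over a shared site universe, each site is scored
by its normalized tag density in a +-100 bp window around the summit; the
resulting per-dataset vectors are compared by pairwise Spearman rank
correlation (midranks, Pearson on ranks).  Peak sets themselves are compared
by >= 1 bp interval overlap: Venn-style counts are reported from both sides
because overlap is many-to-many, and a union/intersection site universe can
be built for downstream scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ValidationError
from .genome_io import CoverageTrack, PeakSet
from .signal_profiles import region_intensity


def summit_density_vector(
    track: CoverageTrack, sites: PeakSet, half_width: int = 100, scale: float = 1.0
) -> np.ndarray:
    """Mean density over [summit - half_width, summit + half_width) per site."""
    anchors = [
        (row.chrom, int(row.summit)) for row in sites.peaks.itertuples(index=False)
    ]
    return region_intensity(track, anchors, flank=half_width, scale=scale)


@dataclass
class ColocMatrix:
    labels: list[str]
    rho: np.ndarray          # symmetric, unit diagonal
    site_universe: str = ""  # description of the shared binding-site set

    def __post_init__(self) -> None:
        r = self.rho
        if r.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("rho shape must match labels")
        if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
            raise ValidationError("rho must be symmetric with unit diagonal")
        if (np.abs(r) > 1 + 1e-12).any():
            raise ValidationError("|rho| must be <= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.labels, columns=self.labels)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        warnings.warn("constant vector in Spearman; rho defined as 0", stacklevel=3)
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def pairwise_spearman(
    vectors: dict[str, np.ndarray], site_universe: str = ""
) -> ColocMatrix:
    """All-pairs Spearman rho over a common site universe.

    Vectors must share one length >= 3.  A constant vector yields rho = 0
    against everything (with a warning) so the matrix stays total.
    """
    labels = list(vectors)
    if not labels:
        raise ValidationError("no vectors supplied")
    arrays = [np.asarray(vectors[k], dtype=float) for k in labels]
    n = arrays[0].size
    if n < 3:
        raise ValidationError("vectors must have length >= 3")
    if any(a.size != n for a in arrays):
        raise ValidationError("all vectors must share the same length")
    m = len(labels)
    rho = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            rho[i, j] = rho[j, i] = _spearman(arrays[i], arrays[j])
    return ColocMatrix(labels=labels, rho=rho, site_universe=site_universe)


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------


def _trees(peak_set: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in peak_set.peaks.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(int(row.start), int(row.end))
    return trees


def _overlaps_any(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


@dataclass(frozen=True)
class OverlapCounts:
    """Asymmetric Venn counts: overlap is many-to-many, so both anchorings
    are reported rather than a single ambiguous 'shared' number."""

    a_only: int
    a_shared: int
    b_shared: int
    b_only: int


def overlap_counts(set_a: PeakSet, set_b: PeakSet) -> OverlapCounts:
    """Count peaks of each set with >= 1 bp overlap in the other."""
    trees_b = _trees(set_b)
    trees_a = _trees(set_a)
    a_shared = sum(
        _overlaps_any(trees_b, r.chrom, int(r.start), int(r.end))
        for r in set_a.peaks.itertuples(index=False)
    )
    b_shared = sum(
        _overlaps_any(trees_a, r.chrom, int(r.start), int(r.end))
        for r in set_b.peaks.itertuples(index=False)
    )
    return OverlapCounts(
        a_only=len(set_a) - a_shared,
        a_shared=a_shared,
        b_shared=b_shared,
        b_only=len(set_b) - b_shared,
    )


def merge_site_universe(peak_sets, mode: str = "union") -> PeakSet:
    """Build a shared site universe from several peak sets.

    union
        Overlapping intervals (>= 1 bp, across all sets pooled) are merged
        into one site whose summit and score come from the highest-score
        member peak.
    intersection
        Intervals of the *first* set that overlap >= 1 bp with a peak in
        every other set.
    """
    peak_sets = list(peak_sets)
    if not peak_sets:
        raise ValidationError("need at least one peak set")
    if mode not in ("union", "intersection"):
        raise ValidationError(f"unknown mode {mode!r}")

    if mode == "intersection":
        others = [_trees(ps) for ps in peak_sets[1:]]
        keep = [
            row
            for row in peak_sets[0].peaks.itertuples(index=False)
            if all(
                _overlaps_any(t, row.chrom, int(row.start), int(row.end)) for t in others
            )
        ]
        frame = pd.DataFrame(keep, columns=peak_sets[0].peaks.columns)
        return PeakSet(name="intersection", peaks=frame)

    pooled = pd.concat([ps.peaks for ps in peak_sets], ignore_index=True)
    pooled = pooled.sort_values(["chrom", "start"], kind="mergesort")
    merged = []
    current = None  # [chrom, start, end, best_row]
    for row in pooled.itertuples(index=False):
        if current is not None and row.chrom == current[0] and int(row.start) < current[2]:
            current[2] = max(current[2], int(row.end))
            if row.score > current[3].score:
                current[3] = row
        else:
            if current is not None:
                merged.append(current)
            current = [row.chrom, int(row.start), int(row.end), row]
        # summit of the best member may lie outside after clipping never occurs:
        # merged interval only grows, so the member summit stays inside
    if current is not None:
        merged.append(current)
    frame = pd.DataFrame(
        [
            (c, s, e, best.name, best.score, int(best.summit))
            for c, s, e, best in merged
        ],
        columns=["chrom", "start", "end", "name", "score", "summit"],
    )
    return PeakSet(name="union", peaks=frame)
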