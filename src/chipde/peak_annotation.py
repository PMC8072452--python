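"""Peak-to-gene assignment by nearest TSS.

Each binding site is anchored at its summit and assigned the gene whose
transcription start site minimizes ``|summit - tss|`` on the same chromosome
(ties broken by lexicographically smallest gene_id; cross-chromosome distance
is undefined).  Sites are then classified gene-proximal or gene-distal at an
inclusive distance threshold (1 kb by default) and can be ranked by distance
for heatmap-style displays.  The dual query — which genes have at least one
summit within a window of their TSS — drives the cluster-enrichment stage.

Distances are strand-agnostic in magnitude; the signed distance (negative =
upstream in gene orientation) is carried for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import GenomeAnnotation, PeakSet

PROXIMAL = "proximal"
DISTAL = "distal"

ANNOTATED_COLUMNS = [
    "peak_id",
    "chrom",
    "summit",
    "nearest_gene",
    "distance",
    "signed_distance",
    "proximity",
]


@dataclass(frozen=True)
class ProximitySummary:
    """Counts of gene-proximal vs gene-distal sites among assigned peaks."""

    n_proximal: int
    n_distal: int

    @property
    def n_assigned(self) -> int:
        return self.n_proximal + self.n_distal

    @property
    def proximal_fraction(self) -> float:
        if self.n_assigned == 0:
            raise ValidationError("no assigned peaks")
        return self.n_proximal / self.n_assigned

    @property
    def proximal_percent(self) -> float:
        return 100.0 * self.proximal_fraction


class _TssIndex:
    """Per-chromosome sorted unique-TSS index with min-gene_id tie resolution."""

    def __init__(self, annotation: GenomeAnnotation):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        genes = annotation.genes.sort_values(["tss", "gene_id"], kind="mergesort")
        for chrom, sub in genes.groupby("chrom", sort=False):
            tss = sub["tss"].to_numpy()
            ids = sub["gene_id"].to_numpy()
            strand = sub["strand"].to_numpy()
            # first occurrence per unique tss has the smallest gene_id
            uniq, first = np.unique(tss, return_index=True)
            self.by_chrom[chrom] = (uniq, ids[first], strand[first])


def nearest_tss(peaks: PeakSet, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Assign every peak its nearest-TSS gene and distance.

    Returns a DataFrame with one row per peak (input order preserved):
    peak_id, chrom, summit, nearest_gene, distance, signed_distance.  Peaks on
    chromosomes with no annotated genes get ``nearest_gene = ''`` and distance
    -1 (flagged unassigned).
    """
    if len(annotation) == 0:
        raise ValidationError("empty annotation")
    index = _TssIndex(annotation)
    out = []
    for row in peaks.peaks.itertuples(index=False):
        entry = index.by_chrom.get(row.chrom)
        if entry is None:
            out.append((row.name, row.chrom, int(row.summit), "", -1, 0))
            continue
        uniq, ids, strands = entry
        summit = int(row.summit)
        i = int(np.searchsorted(uniq, summit))
        best = None  # (distance, gene_id, tss, strand)
        for j in (i - 1, i):
            if 0 <= j < len(uniq):
                cand = (abs(summit - int(uniq[j])), str(ids[j]), int(uniq[j]), str(strands[j]))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, gene, tss, strand = best
        signed = summit - tss if strand == "+" else tss - summit
        out.append((row.name, row.chrom, summit, gene, dist, signed))
    return pd.DataFrame(
        out,
        columns=["peak_id", "chrom", "summit", "nearest_gene", "distance", "signed_distance"],
    )


def classify_proximity(
    annotated: pd.DataFrame, proximal_threshold: int = 1000
) -> tuple[pd.DataFrame, ProximitySummary]:
    """Label assigned peaks proximal (distance <= threshold, inclusive) or distal.

    Unassigned peaks (distance < 0) keep an empty label and are excluded from
    the counts; ``n_proximal + n_distal`` equals the number of assigned peaks.
    """
    if "distance" not in annotated.columns:
        raise ValidationError("run nearest_tss first")
    result = annotated.copy()
    assigned = result["distance"] >= 0
    result["proximity"] = ""
    result.loc[assigned & (result["distance"] <= proximal_threshold), "proximity"] = PROXIMAL
    result.loc[assigned & (result["distance"] > proximal_threshold), "proximity"] = DISTAL
    summary = ProximitySummary(
        n_proximal=int((result["proximity"] == PROXIMAL).sum()),
        n_distal=int((result["proximity"] == DISTAL).sum()),
    )
    return result, summary


def rank_by_distance(annotated: pd.DataFrame) -> pd.DataFrame:
    """Stable ascending sort by distance; ties keep input order."""
    if "distance" not in annotated.columns:
        raise ValidationError("run nearest_tss first")
    return annotated.sort_values("distance", kind="mergesort").reset_index(drop=True)


def genes_with_site_within(
    annotation: GenomeAnnotation, peaks: PeakSet, window: int
) -> set[str]:
    """Genes with at least one peak summit within ``window`` bp of their TSS.

    The window is inclusive on both sides: ``|summit - tss| <= window``.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    summits_by_chrom = {
        chrom: np.sort(sub["summit"].to_numpy())
        for chrom, sub in peaks.peaks.groupby("chrom", sort=False)
    }
    hits: set[str] = set()
    for chrom, sub in annotation.genes.groupby("chrom", sort=False):
        summits = summits_by_chrom.get(chrom)
        if summits is None or len(summits) == 0:
            continue
        tss = sub["tss"].to_numpy()
        lo = np.searchsorted(summits, tss - window, side="left")
        hi = np.searchsorted(summits, tss + window, side="right")
        has = hi > lo
        hits.update(sub["gene_id"].to_numpy()[has])
    return hits
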