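#!/usr/bin/env python
"""Assign every binding site its nearest TSS and classify proximity.

Reads the study-scale synthetic inputs from 01_simulate.py, writes the
distance-ranked annotated site table and the proximal/distal summary, and
prints the headline split (the planted structure puts ~74% of sites within
1 kb of a TSS).
"""

from pathlib import Path

import pandas as pd

from chipde import genome_io as gio
from chipde import peak_annotation as pa

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sizes = gio.read_chrom_sizes(DATA / "genome.chrom.sizes")
    annotation = gio.read_annotation(DATA / "annotation.tsv", sizes)
    peaks = gio.read_peaks(DATA / "peaks.narrowPeak", sizes, name="factor")

    annotated = pa.nearest_tss(peaks, annotation)
    annotated, summary = pa.classify_proximity(annotated, proximal_threshold=1000)
    ranked = pa.rank_by_distance(annotated)
    ranked.to_csv(OUT / "annotated_peaks.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{
            "n_proximal": summary.n_proximal,
            "n_distal": summary.n_distal,
            "n_assigned": summary.n_assigned,
            "proximal_percent": round(summary.proximal_percent, 1),
        }]
    ).to_csv(OUT / "proximity_summary.tsv", sep="\t", index=False)

    print(f"{summary.n_assigned} sites: {summary.n_proximal} gene-proximal (<=1 kb), "
          f"{summary.n_distal} gene-distal ({summary.proximal_percent:.1f}% proximal)")
    print(f"distance-ranked table -> {OUT / 'annotated_peaks.tsv'}")


if __name__ == "__main__":
    main()
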