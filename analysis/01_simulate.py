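#!/usr/bin/env python
"""Generate the synthetic study inputs.

Study-scale artifacts (mm9-sized genome, 24,421 genes, 13,163 binding sites
planted 74% TSS-proximal, 916-gene DE table in six clusters) are written as
plain-text standard formats under results/data/.  The coverage tracks, which
are only desk-scale at the documented demo size (5 Mb genome, 300 sites),
are written alongside under results/data/demo/.
"""

from pathlib import Path

from chipde import genome_io as gio
from chipde import synthetic_data as syn

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = syn.SyntheticConfig(seed=SEED)
    annotation = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, annotation)
    de = syn.generate_de_table(cfg, annotation, peaks)
    gio.write_chrom_sizes(cfg.chrom_sizes, OUT / "genome.chrom.sizes")
    gio.write_annotation(annotation, OUT / "annotation.tsv")
    gio.write_peaks(peaks, OUT / "peaks.narrowPeak")
    gio.write_de_table(de, OUT / "de_table.tsv")
    print(f"study scale: {len(annotation)} genes, {len(peaks)} sites, "
          f"{(de.rows['cluster'] != 'none').sum()} cluster genes -> {OUT}")

    demo = OUT / "demo"
    demo.mkdir(exist_ok=True)
    dcfg = syn.demo_config(SEED)
    dann = syn.generate_annotation(dcfg)
    dpeaks = syn.generate_peaks(dcfg, dann)
    dde = syn.generate_de_table(dcfg, dann, dpeaks)
    gio.write_chrom_sizes(dcfg.chrom_sizes, demo / "genome.chrom.sizes")
    gio.write_annotation(dann, demo / "annotation.tsv")
    gio.write_peaks(dpeaks, demo / "peaks.narrowPeak")
    gio.write_de_table(dde, demo / "de_table.tsv")
    for cond in syn.CONDITIONS:
        for mark in syn.MARKS:
            track = syn.generate_coverage(dcfg, dpeaks, cond, mark)
            gio.write_coverage(track, demo / f"coverage_{cond}_{mark}.bedGraph")
            print(f"demo scale: {track.name} libsize {track.libsize}")


if __name__ == "__main__":
    main()
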