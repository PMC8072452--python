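#!/usr/bin/env python
"""Call significant genes and assign expression-pattern clusters I-VI.

Applies the |FC| >= 1.5, BH-FDR <= 0.01 rule to both contrasts of the
study-scale DE table and groups significant genes by their up/down pattern
(pre-B x immature B).  Writes the labeled table and the per-cluster counts.
"""

from pathlib import Path

import pandas as pd

from chipde import expression_prep as ep
from chipde import genome_io as gio

DATA = Path("results/data")
OUT = Path("results/tables")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    de = gio.read_de_table(DATA / "de_table.tsv")
    assigned = ep.assign_clusters(de, fc_threshold=1.5, fdr_threshold=0.01)

    gio.write_de_table(assigned.table, OUT / "de_clusters.tsv")
    counts = pd.DataFrame(sorted(assigned.counts.items()), columns=["cluster", "n_genes"])
    counts.loc[len(counts)] = ["discordant", assigned.n_discordant]
    counts.to_csv(OUT / "cluster_counts.tsv", sep="\t", index=False)

    print(f"{assigned.n_significant} significant genes "
          f"({assigned.n_discordant} discordant, excluded from clusters)")
    for label, n in sorted(assigned.counts.items()):
        print(f"  cluster {label}: {n}")


if __name__ == "__main__":
    main()
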