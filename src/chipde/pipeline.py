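"""End-to-end orchestration with declarative config and deterministic seeding.

``run_all`` executes the stages — simulate, prep-expression, annotate,
profile, colocalize, enrich — writing every intermediate as a plain-text
standard format (so any stage can be fed external real data instead), plus a
manifest recording parameters, package version, and the SHA-256 of every
output.  One master seed is fanned out to named child streams per stage;
rerunning with the same config and seed reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import colocalization, enrichment, expression_prep, peak_annotation, signal_profiles
from . import genome_io as gio
from . import synthetic_data as syn
from .errors import ValidationError

log = logging.getLogger("chipde")

_STAGES = ("simulate", "prep_expression", "annotate", "profile", "colocalize", "enrich")

# child-stream tags for pipeline-level randomness (the synthetic generator
# has its own artifact streams keyed off the same master seed)
_NULL_GENE_STREAM = 101
_NULL_SITE_STREAM = 102


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    preset: str = "demo"                            # demo | study
    proximal_threshold: int = 1000
    windows: list[int] = field(
        default_factory=lambda: [1000, 2500, 5000, 10000, 25000, 50000, 100000]
    )
    flank: int = 2500
    profile_bin_size: int = 25
    half_width: int = 100
    n_null_groups: int = 10
    null_gene_group_size: int = 300
    null_site_group_size: int = 10_000
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.01
    min_cpm: float = 5.0
    min_samples: int = 3
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(_STAGES)
        if bad:
            raise ValidationError(f"unknown stage(s): {sorted(bad)}")
        if cfg.preset not in ("demo", "study"):
            raise ValidationError(f"unknown preset {cfg.preset!r}")
        if list(cfg.windows) != sorted(cfg.windows):
            raise ValidationError("windows must be sorted ascending")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def synthetic_config(self) -> syn.SyntheticConfig:
        base = (
            syn.demo_config(self.seed)
            if self.preset == "demo"
            else syn.SyntheticConfig(seed=self.seed)
        )
        if self.synthetic:
            base = dataclasses.replace(base, **self.synthetic)
        return base.with_seed(self.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages; return the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "outputs": {},
    }

    def record(path: Path) -> None:
        manifest["outputs"][path.name] = _sha256(path)

    scfg = config.synthetic_config()

    # ---- simulate -------------------------------------------------------
    if "simulate" not in config.stages:
        raise ValidationError(
            "run_all currently drives the synthetic demo; enable the simulate stage "
            "or call the stage functions directly on external data"
        )
    log.info("simulate: genome %d x %d bp, %d genes, %d peaks",
             scfg.n_chroms, scfg.chrom_length, scfg.n_genes, scfg.n_peaks)
    annotation = syn.generate_annotation(scfg)
    peaks = syn.generate_peaks(scfg, annotation)
    de = syn.generate_de_table(scfg, annotation, peaks)
    tracks = {
        (cond, mark): syn.generate_coverage(scfg, peaks, cond, mark)
        for cond in syn.CONDITIONS
        for mark in syn.MARKS
    }
    gio.write_chrom_sizes(scfg.chrom_sizes, outdir / "genome.chrom.sizes")
    gio.write_annotation(annotation, outdir / "annotation.tsv")
    gio.write_peaks(peaks, outdir / "peaks.narrowPeak")
    gio.write_de_table(de, outdir / "de_table.tsv")
    for (cond, mark), tr in tracks.items():
        gio.write_coverage(tr, outdir / f"coverage_{cond}_{mark}.bedGraph")
    for name in ["genome.chrom.sizes", "annotation.tsv", "peaks.narrowPeak", "de_table.tsv"]:
        record(outdir / name)
    for cond, mark in tracks:
        record(outdir / f"coverage_{cond}_{mark}.bedGraph")

    # ---- prep-expression ------------------------------------------------
    if "prep_expression" in config.stages:
        assigned = expression_prep.assign_clusters(
            de, config.fc_threshold, config.fdr_threshold
        )
        de = assigned.table
        gio.write_de_table(de, outdir / "de_clusters.tsv")
        counts = pd.DataFrame(
            sorted(assigned.counts.items()), columns=["cluster", "n_genes"]
        )
        counts.loc[len(counts)] = ["discordant", assigned.n_discordant]
        _write_tsv(counts, outdir / "cluster_counts.tsv")
        record(outdir / "de_clusters.tsv")
        record(outdir / "cluster_counts.tsv")
        log.info("prep_expression: %d significant genes, %d discordant",
                 assigned.n_significant, assigned.n_discordant)

    # ---- annotate -------------------------------------------------------
    annotated = None
    if "annotate" in config.stages:
        annotated = peak_annotation.nearest_tss(peaks, annotation)
        annotated, summary = peak_annotation.classify_proximity(
            annotated, config.proximal_threshold
        )
        ranked = peak_annotation.rank_by_distance(annotated)
        _write_tsv(ranked, outdir / "annotated_peaks.tsv")
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "n_proximal": summary.n_proximal,
                        "n_distal": summary.n_distal,
                        "n_assigned": summary.n_assigned,
                        "proximal_percent": summary.proximal_percent,
                    }
                ]
            ),
            outdir / "proximity_summary.tsv",
        )
        record(outdir / "annotated_peaks.tsv")
        record(outdir / "proximity_summary.tsv")
        log.info("annotate: %d proximal / %d distal (%.1f%%)",
                 summary.n_proximal, summary.n_distal, summary.proximal_percent)

    # ---- profile --------------------------------------------------------
    if "profile" in config.stages:
        if annotated is None:
            raise ValidationError("profile stage requires the annotate stage")
        prox = annotated[annotated["proximity"] == peak_annotation.PROXIMAL]
        groups = {"proximal": prox}
        dist = annotated[annotated["proximity"] == peak_annotation.DISTAL]
        if len(dist):
            groups["distal"] = dist
        profile_rows = []
        for (cond, mark), tr in tracks.items():
            norm = signal_profiles.normalize_track(tr)
            for gname, sub in groups.items():
                anchors = list(zip(sub["chrom"], sub["summit"]))
                if not anchors:
                    continue
                pm = signal_profiles.profile_matrix(
                    norm, anchors, flank=config.flank, bin_size=config.profile_bin_size
                )
                means, se = signal_profiles.average_profile(pm)
                for off, m, s in zip(pm.bin_offsets, means, se):
                    profile_rows.append(
                        {
                            "dataset": f"{cond}_{mark}",
                            "site_group": gname,
                            "bin_offset": int(off),
                            "mean": m,
                            "se": s,
                        }
                    )
        _write_tsv(pd.DataFrame(profile_rows), outdir / "profiles.tsv")
        record(outdir / "profiles.tsv")

        anchors = list(zip(peaks.peaks["chrom"], peaks.peaks["summit"]))
        wt = signal_profiles.normalize_track(tracks[("WT", "histone_mark")])
        ko = signal_profiles.normalize_track(tracks[("KO", "histone_mark")])
        wt_i = signal_profiles.region_intensity(wt, anchors, flank=config.flank)
        ko_i = signal_profiles.region_intensity(ko, anchors, flank=config.flank)
        u, p = signal_profiles.compare_intensities(ko_i, wt_i)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "comparison": "KO_vs_WT_histone_mark",
                        "n_sites": len(anchors),
                        "median_WT": float(np.median(wt_i)),
                        "median_KO": float(np.median(ko_i)),
                        "mannwhitney_U": u,
                        "p_two_sided": p,
                    }
                ]
            ),
            outdir / "intensity_comparison.tsv",
        )
        record(outdir / "intensity_comparison.tsv")
        log.info("profile: KO vs WT mark intensity p = %.3g", p)

    # ---- colocalize -----------------------------------------------------
    if "colocalize" in config.stages:
        vectors = {
            f"{cond}_{mark}": colocalization.summit_density_vector(
                signal_profiles.normalize_track(tr), peaks, half_width=config.half_width
            )
            for (cond, mark), tr in tracks.items()
        }
        coloc = colocalization.pairwise_spearman(
            vectors, site_universe=f"{len(peaks)} factor sites"
        )
        coloc.to_frame().to_csv(
            outdir / "spearman_matrix.tsv", sep="\t", float_format="%.10g"
        )
        record(outdir / "spearman_matrix.tsv")

        rand = enrichment.random_binding_sites(
            scfg.chrom_sizes,
            n_groups=1,
            group_size=len(peaks),
            site_width=syn.PEAK_WIDTH,
            seed=np.random.SeedSequence([config.seed, _NULL_SITE_STREAM, 1]),
        )[0]
        oc = colocalization.overlap_counts(peaks, rand)
        _write_tsv(
            pd.DataFrame(
                [
                    {
                        "set_a": peaks.name,
                        "set_b": rand.name,
                        "a_only": oc.a_only,
                        "a_shared": oc.a_shared,
                        "b_shared": oc.b_shared,
                        "b_only": oc.b_only,
                    }
                ]
            ),
            outdir / "overlap_counts.tsv",
        )
        record(outdir / "overlap_counts.tsv")

    # ---- enrich ---------------------------------------------------------
    if "enrich" in config.stages:
        universe = annotation.gene_ids()
        gene_groups = enrichment.random_gene_clusters(
            universe,
            n_groups=config.n_null_groups,
            group_size=min(config.null_gene_group_size, len(universe)),
            seed=np.random.SeedSequence([config.seed, _NULL_GENE_STREAM]),
        )
        site_groups = enrichment.random_binding_sites(
            scfg.chrom_sizes,
            n_groups=config.n_null_groups,
            group_size=config.null_site_group_size,
            site_width=syn.PEAK_WIDTH,
            seed=np.random.SeedSequence([config.seed, _NULL_SITE_STREAM]),
        )
        rows = []
        for label in gio.CLUSTER_LABELS:
            genes = de.cluster_genes(label)
            if not genes:
                continue
            report = enrichment.cluster_enrichment(
                genes,
                annotation,
                peaks,
                config.windows,
                gene_groups,
                site_groups,
                cluster_label=label,
            )
            for _, r in report.table.iterrows():
                rows.append(
                    {
                        "cluster": label,
                        "window_bp": r["window_bp"],
                        "n_genes": r["n_genes"],
                        "n_with_site": r["n_with_site"],
                        "fraction": r["fraction"],
                        "null_gene_mean": r["null_gene_mean"],
                        "null_site_mean": r["null_site_mean"],
                        "null_gene_fractions": ",".join(
                            f"{x:.6g}" for x in r["null_gene_fractions"]
                        ),
                        "null_site_fractions": ",".join(
                            f"{x:.6g}" for x in r["null_site_fractions"]
                        ),
                        "fisher_p_vs_random_genes": r["fisher_p_vs_random_genes"],
                        "fisher_p_vs_random_sites": r["fisher_p_vs_random_sites"],
                    }
                )
        _write_tsv(pd.DataFrame(rows), outdir / "enrichment.tsv")
        record(outdir / "enrichment.tsv")
        log.info("enrich: %d cluster x window rows", len(rows))

    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
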