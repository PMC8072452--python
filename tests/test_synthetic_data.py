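"""Planted-structure generators: determinism, bounds, and recoverable truth."""

import dataclasses
import io
import math

import numpy as np
import pytest

from chipde import expression_prep, genome_io as gio, peak_annotation as pa
from chipde import synthetic_data as syn
from chipde.errors import SizingError, ValidationError
from conftest import small_config


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_genes": 0},
        {"proximal_fraction": 1.5},
        {"bg_rate": -1.0},
        {"peak_fold": 0.5},
        {"cluster_sizes": {"V": 10_000}},  # exceeds n_genes
        {"n_genes": 50_000},  # genome too small for density
    ],
)
def test_config_rejects_invalid(overrides):
    with pytest.raises((ValidationError, SizingError)):
        small_config(**overrides)


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_same_seed_reproduces_identical_artifacts(tmp_path):
    cfg = small_config(seed=5)
    outputs = []
    for run in range(2):
        ann = syn.generate_annotation(cfg)
        peaks = syn.generate_peaks(cfg, ann)
        de = syn.generate_de_table(cfg, ann, peaks)
        cov = syn.generate_coverage(cfg, peaks, "KO", "histone_mark")
        buf = {}
        gio.write_annotation(ann, tmp_path / f"a{run}.tsv")
        gio.write_peaks(peaks, tmp_path / f"p{run}.narrowPeak")
        gio.write_de_table(de, tmp_path / f"d{run}.tsv")
        gio.write_coverage(cov, tmp_path / f"c{run}.bedGraph")
        outputs.append(
            tuple((tmp_path / f"{k}{run}{ext}").read_bytes()
                  for k, ext in [("a", ".tsv"), ("p", ".narrowPeak"),
                                 ("d", ".tsv"), ("c", ".bedGraph")])
        )
    assert outputs[0] == outputs[1]


def test_different_seed_changes_peaks():
    c1, c2 = small_config(seed=1), small_config(seed=2)
    a1, a2 = syn.generate_annotation(c1), syn.generate_annotation(c2)
    assert not syn.generate_peaks(c1, a1) == syn.generate_peaks(c2, a2)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def test_annotation_tss_within_bounds_and_unique_ids():
    cfg = syn.SyntheticConfig(
        seed=3, n_chroms=2, chrom_length=1_000_000, n_genes=1000,
        n_peaks=10, cluster_sizes={}, association_prob={},
    )
    ann = syn.generate_annotation(cfg)
    assert len(ann) == 1000
    assert ann.genes["gene_id"].is_unique
    for chrom, sub in ann.genes.groupby("chrom"):
        assert sub["tss"].between(0, cfg.chrom_length - 1).all()
    # fair-coin strand: 3 binomial SD
    n_plus = (ann.genes["strand"] == "+").sum()
    assert abs(n_plus - 500) < 3 * math.sqrt(1000 * 0.25)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def test_all_planted_proximal_classifies_proximal():
    cfg = small_config(seed=7, proximal_fraction=1.0, n_peaks=60)
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    annotated = pa.nearest_tss(peaks, ann)
    _, summary = pa.classify_proximity(annotated, cfg.proximal_threshold)
    assert summary.n_proximal == len(peaks)
    assert summary.n_distal == 0


def test_summit_inside_interval_and_bounds(demo_peaks, demo_cfg):
    p = demo_peaks.peaks
    assert ((p["start"] <= p["summit"]) & (p["summit"] < p["end"])).all()
    demo_peaks.validate_bounds(demo_cfg.chrom_sizes)


def test_planted_proximal_fraction_recovered_mid_scale():
    cfg = syn.SyntheticConfig(
        seed=13, n_chroms=2, chrom_length=30_000_000, n_genes=1000,
        n_peaks=2000, proximal_fraction=0.74,
        cluster_sizes={}, association_prob={},
    )
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    annotated = pa.nearest_tss(peaks, ann)
    _, summary = pa.classify_proximity(annotated, 1000)
    sd = math.sqrt(0.74 * 0.26 / cfg.n_peaks)
    # planted fraction plus a small accidental-proximity excess from the
    # uniform 26%; the band check tolerates both
    assert abs(summary.proximal_fraction - 0.74) < 3 * sd + 0.26 * 0.07


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def test_background_only_coverage_mean():
    cfg = small_config(seed=9, peak_fold=1.0, bg_rate=2.0)
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    tr = syn.generate_coverage(cfg, peaks, "WT", "factor")
    vals = np.concatenate(list(tr.values.values()))
    se = math.sqrt(2.0 / vals.size)
    assert abs(vals.mean() - 2.0) < 3 * se


def test_zero_rate_gives_zero_track():
    cfg = small_config(seed=9, bg_rate=0.0, peak_fold=1.0)
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    tr = syn.generate_coverage(cfg, peaks, "WT", "factor")
    assert all(np.all(v == 0) for v in tr.values.values())
    assert tr.libsize == 1  # floored to keep downstream normalization defined


def test_ko_mark_amplitude_scales_at_sites():
    cfg = small_config(seed=21, n_peaks=30, bg_rate=2.0, peak_fold=6.0,
                      ko_mark_fold=3.0, chrom_length=500_000)
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    wt = syn.generate_coverage(cfg, peaks, "WT", "histone_mark")
    ko = syn.generate_coverage(cfg, peaks, "KO", "histone_mark")
    # mean count in the summit bin across sites: background + amplitude vs
    # background + 3x amplitude
    def summit_mean(tr):
        vals = []
        for row in peaks.peaks.itertuples(index=False):
            vals.append(tr.values[row.chrom][int(row.summit) // cfg.bin_size])
        return np.mean(vals)

    amp = cfg.bg_rate * (cfg.peak_fold - 1)
    assert summit_mean(wt) == pytest.approx(cfg.bg_rate + amp, rel=0.35)
    assert summit_mean(ko) == pytest.approx(cfg.bg_rate + 3 * amp, rel=0.35)


def test_coverage_rejects_bad_labels(demo_cfg, demo_peaks):
    with pytest.raises(ValidationError):
        syn.generate_coverage(demo_cfg, demo_peaks, "XX", "factor")
    with pytest.raises(ValidationError):
        syn.generate_coverage(demo_cfg, demo_peaks, "WT", "h3k4me3")


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------


def test_planted_clusters_recovered_by_assignment(demo_cfg, demo_de):
    assigned = expression_prep.assign_clusters(demo_de)
    assert assigned.table.rows["cluster"].tolist() == demo_de.rows["cluster"].tolist()
    assert assigned.counts == {
        lab: demo_cfg.cluster_sizes.get(lab, 0) for lab in gio.CLUSTER_LABELS
    }
    assert assigned.n_discordant == 0


def test_empty_cluster_sizes_gives_no_significant_genes():
    cfg = small_config(seed=4, cluster_sizes={}, association_prob={})
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    de = syn.generate_de_table(cfg, ann, peaks)
    assigned = expression_prep.assign_clusters(de)
    assert assigned.n_significant == 0


def test_cluster_sizes_exceeding_proximal_pool_raise():
    # 1 peak cannot make 40 genes proximal; association 1.0 demands it
    cfg = small_config(seed=4, n_peaks=1, cluster_sizes={"V": 40},
                      association_prob={"V": 1.0})
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    with pytest.raises(SizingError):
        syn.generate_de_table(cfg, ann, peaks)


def test_association_planting_enriches_cluster():
    cfg = syn.SyntheticConfig(
        seed=17, n_chroms=2, chrom_length=30_000_000, n_genes=3000,
        n_peaks=745, proximal_fraction=0.9,
        cluster_sizes={"V": 300}, association_prob={"V": 0.6},
    )
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    de = syn.generate_de_table(cfg, ann, peaks)
    prox = pa.genes_with_site_within(ann, peaks, cfg.proximal_threshold)
    cluster = de.cluster_genes("V")
    frac = len(cluster & prox) / len(cluster)
    assert abs(frac - 0.6) < 3 * math.sqrt(0.6 * 0.4 / 300)
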