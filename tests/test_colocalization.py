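"""Summit-density vectors, Spearman matrices, and peak-set overlap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chipde import colocalization as coloc
from chipde import signal_profiles as sp
from chipde import synthetic_data as syn
from chipde.errors import ValidationError
from chipde.genome_io import CoverageTrack, PeakSet
from conftest import small_config


def _peaks(intervals, name="t"):
    frame = pd.DataFrame(
        [(c, s, e, f"{name}_{i}", float(i), (s + e) // 2)
         for i, (c, s, e) in enumerate(intervals)],
        columns=["chrom", "start", "end", "name", "score", "summit"],
    )
    return PeakSet(name=name, peaks=frame)


# ---------------------------------------------------------------------------
# summit density
# ---------------------------------------------------------------------------


def test_constant_track_gives_constant_vector():
    tr = CoverageTrack("t", 25, {"chr1": np.full(400, 2.5)}, 10_000_000,
                       chrom_sizes={"chr1": 10_000})
    sites = _peaks([("chr1", 4800, 5200), ("chr1", 7800, 8200)])
    assert np.allclose(coloc.summit_density_vector(tr, sites), 2.5)


def test_summit_density_equals_region_intensity_at_flank_100():
    rng = np.random.default_rng(0)
    tr = CoverageTrack("t", 25, {"chr1": rng.uniform(0, 5, 400)}, 10_000_000,
                       chrom_sizes={"chr1": 10_000})
    sites = _peaks([("chr1", 4800, 5200), ("chr1", 7800, 8200)])
    anchors = [(r.chrom, int(r.summit)) for r in sites.peaks.itertuples(index=False)]
    assert np.allclose(
        coloc.summit_density_vector(tr, sites, half_width=100),
        sp.region_intensity(tr, anchors, flank=100),
    )


def test_coenriched_tracks_high_rho_independent_tracks_low():
    cfg = small_config(seed=31, n_peaks=120, chrom_length=2_000_000, bg_rate=2.0,
                      peak_fold=8.0)
    ann = syn.generate_annotation(cfg)
    peaks = syn.generate_peaks(cfg, ann)
    # same peak set, independent noise: two conditions of the factor track
    t1 = syn.generate_coverage(cfg, peaks, "WT", "factor")
    t2 = syn.generate_coverage(cfg, peaks, "KO", "factor")
    # independent peak set: its track is unrelated to the first set's summits
    cfg2 = small_config(seed=77, n_peaks=120, chrom_length=2_000_000, bg_rate=2.0,
                       peak_fold=8.0)
    peaks2 = syn.generate_peaks(cfg2, syn.generate_annotation(cfg2))
    t3 = syn.generate_coverage(cfg2, peaks2, "WT", "factor")
    vectors = {
        "rep1": coloc.summit_density_vector(t1, peaks),
        "rep2": coloc.summit_density_vector(t2, peaks),
        "indep": coloc.summit_density_vector(t3, peaks),
    }
    m = coloc.pairwise_spearman(vectors)
    frame = m.to_frame()
    assert frame.loc["rep1", "rep2"] > 0.5
    assert abs(frame.loc["rep1", "indep"]) < 0.3


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def test_self_correlation_is_one():
    v = np.array([3.0, 1.0, 2.0, 5.0])
    m = coloc.pairwise_spearman({"a": v, "b": v.copy()})
    assert m.to_frame().loc["a", "b"] == pytest.approx(1.0)


def test_reversed_ranks_give_minus_one():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    m = coloc.pairwise_spearman({"a": v, "b": v[::-1].copy()})
    assert m.to_frame().loc["a", "b"] == pytest.approx(-1.0)


def test_worked_example_minus_half():
    m = coloc.pairwise_spearman(
        {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([3.0, 1.0, 2.0])}
    )
    # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 6
    assert m.to_frame().loc["a", "b"] == pytest.approx(-0.5)


def test_constant_vector_rho_zero_with_warning():
    with pytest.warns(UserWarning):
        m = coloc.pairwise_spearman(
            {"a": np.array([1.0, 1.0, 1.0]), "b": np.array([1.0, 2.0, 3.0])}
        )
    frame = m.to_frame()
    assert frame.loc["a", "b"] == 0.0
    assert frame.loc["a", "a"] == 1.0  # diagonal stays 1 even for constants


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(8)
    for _ in range(25):
        x = rng.integers(0, 5, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=30).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        m = coloc.pairwise_spearman({"x": x, "y": y})
        ref = stats.spearmanr(x, y).statistic
        assert m.to_frame().loc["x", "y"] == pytest.approx(ref, abs=1e-12)


def test_mismatched_lengths_rejected():
    with pytest.raises(ValidationError):
        coloc.pairwise_spearman({"a": np.ones(4), "b": np.ones(5)})


def test_short_vectors_rejected():
    with pytest.raises(ValidationError):
        coloc.pairwise_spearman({"a": np.ones(2), "b": np.ones(2)})


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------


def brute_force_shared(set_a, set_b):
    count = 0
    for a in set_a.peaks.itertuples(index=False):
        for b in set_b.peaks.itertuples(index=False):
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                count += 1
                break
    return count


def test_subset_has_no_a_only():
    a = _peaks([("chr1", 100, 200)])
    b = _peaks([("chr1", 50, 250), ("chr1", 400, 500)])
    oc = coloc.overlap_counts(a, b)
    assert oc.a_only == 0
    assert oc.a_shared == 1
    assert oc.b_only == 1


def test_disjoint_sets_share_nothing():
    a = _peaks([("chr1", 100, 200)])
    b = _peaks([("chr1", 200, 300)])  # touching, not overlapping
    oc = coloc.overlap_counts(a, b)
    assert oc.a_shared == 0 and oc.b_shared == 0


def test_overlap_matches_brute_force():
    rng = np.random.default_rng(9)
    def random_set(name):
        ivs = []
        for _ in range(60):
            s = int(rng.integers(0, 9000))
            ivs.append((f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(50, 400))))
        return _peaks(ivs, name)
    a, b = random_set("a"), random_set("b")
    oc = coloc.overlap_counts(a, b)
    assert oc.a_shared == brute_force_shared(a, b)
    assert oc.b_shared == brute_force_shared(b, a)
    assert oc.a_only + oc.a_shared == len(a)


# ---------------------------------------------------------------------------
# site universe merging
# ---------------------------------------------------------------------------


def test_union_of_disjoint_sets_keeps_all():
    a = _peaks([("chr1", 100, 200)], "a")
    b = _peaks([("chr1", 300, 400)], "b")
    assert len(coloc.merge_site_universe([a, b], "union")) == 2


def test_identical_sets_union_equals_intersection():
    a = _peaks([("chr1", 100, 200), ("chr2", 300, 400)], "a")
    b = _peaks([("chr1", 100, 200), ("chr2", 300, 400)], "b")
    assert len(coloc.merge_site_universe([a, b], "union")) == 2
    assert len(coloc.merge_site_universe([a, b], "intersection")) == 2


def test_union_merges_overlaps_keeps_best_summit():
    a = _peaks([("chr1", 100, 300)], "a")          # score 0
    b = _peaks([("chr1", 250, 500)], "b")          # score 0 -> tie by order; bump
    b.peaks.loc[0, "score"] = 9.0
    merged = coloc.merge_site_universe([a, b], "union")
    assert len(merged) == 1
    row = merged.peaks.iloc[0]
    assert (row["start"], row["end"]) == (100, 500)
    assert row["summit"] == b.peaks["summit"].iloc[0]


def test_union_count_matches_interval_merge_oracle():
    rng = np.random.default_rng(10)
    ivs = []
    for _ in range(100):
        s = int(rng.integers(0, 9500))
        ivs.append(("chr1", s, s + int(rng.integers(10, 300))))
    merged = coloc.merge_site_universe([_peaks(ivs)], "union")
    # oracle: classic sweep over sorted intervals
    expected = 0
    cur_end = -1
    for s, e in sorted((s, e) for _, s, e in ivs):
        if s >= cur_end:
            expected += 1
            cur_end = e
        else:
            cur_end = max(cur_end, e)
    assert len(merged) == expected


def test_intersection_requires_overlap_in_every_set():
    a = _peaks([("chr1", 100, 200), ("chr1", 500, 600)], "a")
    b = _peaks([("chr1", 150, 250)], "b")
    c = _peaks([("chr1", 120, 180), ("chr1", 550, 650)], "c")
    inter = coloc.merge_site_universe([a, b, c], "intersection")
    assert len(inter) == 1
    assert inter.peaks["start"].iloc[0] == 100


def test_unknown_mode_rejected():
    with pytest.raises(ValidationError):
        coloc.merge_site_universe([_peaks([("chr1", 0, 10)])], "xor")
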