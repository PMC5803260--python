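"""Windowed quantification against independent per-base oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from breakscape import (
    CoverageTrack,
    average_profile,
    boxplot_summary,
    compare_cut_uncut,
    compare_paired,
    genes_near_dsb,
    heatmap_matrix,
    metagene_profile,
    quantify_sites,
    stratify_by_transcription,
    window_count,
)
from conftest import make_sites


# --- independent oracles -------------------------------------------------

def brute_window(arr, center, halfwidth, statistic):
    """Per-base python-loop window statistic (truncated at ends)."""
    total, n = 0.0, 0
    for pos in range(center - halfwidth, center + halfwidth):
        if 0 <= pos < len(arr):
            total += float(arr[pos])
            n += 1
    return total if statistic == "sum" else total / n


def exact_mannwhitney_p(x, y):
    """Two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = list(x) + list(y)
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    observed = u_stat(x, y)
    mean_u = n_x * len(y) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


# --- window_count --------------------------------------------------------

def test_window_count_examples():
    arr = np.zeros(100)
    arr[40:60] = 1.0
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    assert window_count(t, "chr1", 50, 10, "sum") == 20.0
    zero = CoverageTrack(values={"chr1": np.zeros(100)}, library_size=1.0)
    assert window_count(zero, "chr1", 50, 30, "sum") == 0.0
    ones = CoverageTrack(values={"chr1": np.ones(100)}, library_size=1.0)
    assert window_count(ones, "chr1", 5, 10, "sum") == 15.0  # truncated [0,15)
    assert window_count(ones, "chr1", 5, 10, "mean") == 1.0


def test_window_count_errors(flat_track):
    with pytest.raises(KeyError, match="chrX"):
        window_count(flat_track, "chrX", 50, 10)
    with pytest.raises(ValueError, match="off chromosome"):
        window_count(flat_track, "chr1", 500, 10)
    with pytest.raises(ValueError, match="halfwidth"):
        window_count(flat_track, "chr1", 50, 0)


def test_window_count_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(1000):
        n = int(rng.integers(20, 200))
        arr = rng.poisson(2.0, n).astype(float)
        t = CoverageTrack(values={"c": arr}, library_size=1.0)
        center = int(rng.integers(0, n))
        hw = int(rng.integers(1, 40))
        if center + hw <= 0 or center - hw >= n:
            continue
        stat = ["sum", "mean"][int(rng.integers(2))]
        assert window_count(t, "c", center, hw, stat) == \
            pytest.approx(brute_window(arr, center, hw, stat), abs=0)


# --- quantify_sites ------------------------------------------------------

def test_quantify_constant_track():
    t = CoverageTrack(values={"chr1": np.full(1000, 3.0)}, library_size=1.0)
    q = quantify_sites(t, make_sites(300, 500, 700), halfwidth=50)
    assert (q["signal"] == 2 * 50 * 3.0).all()
    assert q["cut"].all()


def test_quantify_matches_brute_force_random():
    rng = np.random.default_rng(8)
    arr = rng.poisson(1.5, 5000).astype(float)
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    sites = make_sites(*rng.integers(0, 5000, size=50).tolist())
    sites = sites.drop_duplicates("position")
    q = quantify_sites(t, sites, halfwidth=200)
    for s in sites.itertuples():
        assert q.loc[s.site_id, "signal"] == \
            brute_window(arr, int(s.position), 200, "sum")


def test_quantify_rejects_duplicate_ids(flat_track):
    sites = make_sites(10, 20)
    sites["site_id"] = ["a", "a"]
    with pytest.raises(ValueError, match="duplicate site id"):
        quantify_sites(flat_track, sites, 5)


# --- compare_cut_uncut ---------------------------------------------------

def _quants(cut_vals, uncut_vals):
    rows = [dict(site_id=f"c{i}", cut=True, signal=v)
            for i, v in enumerate(cut_vals)]
    rows += [dict(site_id=f"u{i}", cut=False, signal=v)
             for i, v in enumerate(uncut_vals)]
    return pd.DataFrame(rows).set_index("site_id")


def test_mannwhitney_exact_matches_enumeration():
    cut, uncut = [10, 12, 14], [1, 2, 3]
    r = compare_cut_uncut(_quants(cut, uncut))
    assert r.method == "exact"
    assert r.statistic == 9.0
    assert r.p_value == pytest.approx(0.1)
    assert r.p_value == pytest.approx(exact_mannwhitney_p(cut, uncut))
    assert r.direction == "cut"


def test_mannwhitney_random_small_groups_match_enumeration():
    """Tie-free small groups: p equals the full labeling enumeration."""
    rng = np.random.default_rng(3)
    done = 0
    while done < 20:
        cut = rng.normal(size=int(rng.integers(3, 7))).round(3).tolist()
        uncut = rng.normal(size=int(rng.integers(3, 7))).round(3).tolist()
        if len(set(cut + uncut)) < len(cut) + len(uncut):
            continue  # exact enumeration contract applies to tie-free data
        r = compare_cut_uncut(_quants(cut, uncut))
        assert r.method == "exact"
        assert r.p_value == pytest.approx(exact_mannwhitney_p(cut, uncut),
                                          abs=1e-9)
        done += 1


def test_mannwhitney_identical_groups():
    """Fully tied groups fall back to the tie-corrected approximation."""
    r = compare_cut_uncut(_quants([1, 2, 3], [1, 2, 3]))
    assert r.p_value == pytest.approx(1.0)
    assert r.direction == "none"


def test_mannwhitney_empty_group_is_error():
    with pytest.raises(ValueError, match="non-empty"):
        compare_cut_uncut(_quants([1.0], []))


def test_paired_wilcoxon_detects_shift():
    rng = np.random.default_rng(4)
    before = rng.normal(0, 1, 40)
    _stat, p_null = compare_paired(before, before + rng.normal(0, 1, 40))
    _stat, p_shift = compare_paired(before, before + 2.0)
    assert p_shift < 0.001 < p_null


# --- stratification ------------------------------------------------------

def _score_frame(scores):
    return pd.DataFrame(
        dict(score=scores),
        index=pd.Index([f"s{i:03d}" for i in range(len(scores))],
                       name="site_id"),
    )


def test_stratify_80_sites_four_classes_of_20():
    rng = np.random.default_rng(5)
    out = stratify_by_transcription(_score_frame(rng.normal(size=80)), "score")
    counts = out["transcription_class"].value_counts()
    assert sorted(counts) == [20, 20, 20, 20]


def test_stratify_orders_low_to_high():
    out = stratify_by_transcription(_score_frame([5, 1, 7, 3, 8, 2, 6, 4]),
                                    "score")
    top = out.sort_values("score").iloc[-2:]
    assert (top["transcription_class"] == "high").all()
    bottom = out.sort_values("score").iloc[:2]
    assert (bottom["transcription_class"] == "low").all()


def test_stratify_remainder_goes_to_lowest_class():
    out = stratify_by_transcription(_score_frame(np.arange(81.0)), "score")
    counts = out["transcription_class"].value_counts()
    assert counts["low"] == 21
    assert counts["medium_low"] == counts["medium_high"] == counts["high"] == 20


def test_stratify_is_a_partition_consistent_with_score():
    rng = np.random.default_rng(6)
    df = _score_frame(rng.integers(0, 5, size=37).astype(float))
    out = stratify_by_transcription(df, "score")
    assert out["transcription_class"].notna().all()
    by_class = out.groupby("transcription_class", observed=False)["score"]
    maxima, minima = by_class.max(), by_class.min()
    for lo, hi in zip(by_class.max().index[:-1], by_class.max().index[1:]):
        assert maxima[lo] <= minima[hi] or np.isnan(maxima[lo])


def test_stratify_rejects_non_numeric():
    df = _score_frame([1.0, 2.0, 3.0, 4.0])
    df["score"] = ["a", "b", "c", "d"]
    with pytest.raises(ValueError, match="non-numeric"):
        stratify_by_transcription(df, "score")


# --- heatmap -------------------------------------------------------------

def test_heatmap_constant_and_geometry():
    t = CoverageTrack(values={"chr1": np.full(20_000, 2.0)}, library_size=1.0)
    m = heatmap_matrix(t, make_sites(10_000), halfwidth=5000, bin_width=500)
    assert m.matrix.shape == (1, 20)
    assert (m.matrix == 2.0).all()


def test_heatmap_conservation_random():
    """Sum over bins of (bin mean x bin width) equals the window sum."""
    rng = np.random.default_rng(9)
    arr = rng.poisson(2.0, 40_000).astype(float)
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    sites = make_sites(*rng.integers(5000, 35_000, 20).tolist())
    sites = sites.drop_duplicates("position")
    m = heatmap_matrix(t, sites, halfwidth=5000, bin_width=500)
    for i, sid in enumerate(m.site_ids):
        pos = int(sites.set_index("site_id").loc[sid, "position"])
        assert (m.matrix[i] * 500).sum() == pytest.approx(
            brute_window(arr, pos, 5000, "sum"), rel=1e-12)


def test_heatmap_ordering_by_cleavage():
    t = CoverageTrack(values={"chr1": np.ones(40_000)}, library_size=1.0)
    sites = make_sites(10_000, 20_000, 30_000)  # eff 1.0, 0.9, 0.8
    m = heatmap_matrix(t, sites, halfwidth=5000, bin_width=500)
    assert m.site_ids == ["s1", "s2", "s3"]


def test_heatmap_indivisible_bins_rejected(flat_track):
    with pytest.raises(ValueError, match="divisible"):
        heatmap_matrix(flat_track, make_sites(50), halfwidth=30, bin_width=7)


# --- average profile -----------------------------------------------------

def test_average_profile_single_site_identity():
    rng = np.random.default_rng(10)
    arr = rng.poisson(3.0, 2000).astype(float)
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    p = average_profile(t, make_sites(1000), halfwidth=100, resolution=1)
    np.testing.assert_array_equal(p.mean, arr[900:1100])
    assert (p.n == 1).all()


def test_average_profile_mirror_symmetry():
    arr = np.zeros(4000)
    ramp = np.arange(200.0)
    arr[900:1100] = ramp                 # site 1 at 1000
    arr[2900:3100] = ramp[::-1]          # site 2 at 3000, mirrored
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    p = average_profile(t, make_sites(1000, 3000), halfwidth=100)
    np.testing.assert_allclose(p.mean, p.mean[::-1])


def test_average_profile_truncation_denominators():
    t = CoverageTrack(values={"chr1": np.ones(100)}, library_size=1.0)
    p = average_profile(t, make_sites(10, 50), halfwidth=30)
    # offsets [-30,-20) are off-chromosome for the site at 10
    assert p.n[0] == 1 and p.n[-1] == 2
    assert np.nanmax(p.mean) == 1.0 and np.nanmin(p.mean) == 1.0


# --- metagene ------------------------------------------------------------

GENE = dict(chrom="chr1", start=5000, end=6000, strand="+")


def test_metagene_constant_track_all_bins_flat():
    t = CoverageTrack(values={"chr1": np.full(20_000, 3.0)}, library_size=1.0)
    mg = metagene_profile(t, [GENE])
    assert len(mg.upstream) == len(mg.downstream) == 15
    assert len(mg.body) == 100
    np.testing.assert_allclose(mg.values, 3.0)


def test_metagene_half_covered_gene_bins():
    arr = np.zeros(20_000)
    arr[5000:5500] = 1.0  # first half of the gene body
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    mg = metagene_profile(t, [GENE])
    np.testing.assert_allclose(mg.body[:50], 1.0)
    np.testing.assert_allclose(mg.body[50:], 0.0)
    minus = metagene_profile(t, [dict(GENE, strand="-")])
    np.testing.assert_allclose(minus.body, mg.body[::-1])
    np.testing.assert_allclose(minus.upstream, mg.downstream[::-1])


def test_metagene_matches_brute_force_random():
    rng = np.random.default_rng(11)
    arr = rng.poisson(2.0, 30_000).astype(float)
    t = CoverageTrack(values={"chr1": arr}, library_size=1.0)
    for _ in range(50):
        start = int(rng.integers(4000, 10_000))
        L = int(rng.integers(150, 8000))
        mg = metagene_profile(t, [dict(chrom="chr1", start=start,
                                       end=start + L, strand="+")])
        # independent floor-edge binning
        expected = [arr[start + (b * L) // 100:
                        start + ((b + 1) * L) // 100].mean()
                    for b in range(100)]
        np.testing.assert_allclose(mg.body, expected, rtol=0, atol=0)
        up = [arr[start - 3000 + i * 200: start - 3000 + (i + 1) * 200].mean()
              for i in range(15)]
        np.testing.assert_allclose(mg.upstream, up, rtol=0, atol=0)


def test_metagene_excludes_short_genes_and_errors_when_empty():
    t = CoverageTrack(values={"chr1": np.ones(20_000)}, library_size=1.0)
    short = dict(chrom="chr1", start=5000, end=5050, strand="+")
    mg = metagene_profile(t, [GENE, short])
    assert mg.n_genes == 1 and mg.n_excluded == 1
    with pytest.raises(ValueError, match="no gene long enough"):
        metagene_profile(t, [short])


# --- genes near DSB ------------------------------------------------------

def test_genes_near_dsb_rules():
    genes = pd.DataFrame([
        dict(name="inside", chrom="chr1", start=100, end=200, strand="+"),
        dict(name="at999", chrom="chr1", start=1999, end=2100, strand="+"),
        dict(name="at1000", chrom="chr1", start=4000, end=4100, strand="+"),
        dict(name="near_uncut", chrom="chr1", start=5100, end=5200, strand="+"),
    ])
    sites = pd.DataFrame([
        dict(site_id="a", chrom="chr1", position=150, cut=True),
        dict(site_id="b", chrom="chr1", position=1000, cut=True),
        dict(site_id="c", chrom="chr1", position=3000, cut=True),
        dict(site_id="d", chrom="chr1", position=5150, cut=False),
    ])
    picked = set(genes_near_dsb(genes, sites, max_distance=1000)["name"])
    # gene "at999": edge 1999, site 1000 -> distance 999 -> selected
    # gene "at1000": edge 4000, site 3000 -> distance 1000 -> excluded
    assert picked == {"inside", "at999"}


# --- boxplot summary -----------------------------------------------------

def test_boxplot_worked_example():
    b = boxplot_summary([1, 2, 3, 4, 100])
    assert b.q1 == 2.0 and b.q3 == 4.0 and b.median == 3.0
    assert b.outliers == [100.0]
    assert b.whisker_high == 4.0 and b.whisker_low == 1.0


def test_boxplot_degenerate_and_odd_median():
    b = boxplot_summary([7.0] * 5)
    assert b.outliers == [] and b.whisker_low == b.whisker_high == 7.0
    assert boxplot_summary(range(1, 10)).median == 5.0
    with pytest.raises(ValueError):
        boxplot_summary([])


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
def test_boxplot_invariants(values):
    b = boxplot_summary(values)
    assert b.q1 <= b.median <= b.q3
    iqr = b.q3 - b.q1
    assert b.whisker_low >= b.q1 - 1.5 * iqr - 1e-9
    assert b.whisker_high <= b.q3 + 1.5 * iqr + 1e-9
    assert len(b.outliers) + \
        sum(b.q1 - 1.5 * iqr <= v <= b.q3 + 1.5 * iqr for v in values) \
        == len(values)
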