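"""Site-anchored windowed quantification and profile construction.

Core computations around annotated double-strand-break sites: window
counts, cut-vs-uncut rank statistics, transcription-level stratification,
binned heatmap matrices, base-resolution averaged profiles, metagene
profiles with scaled gene bodies, and Tukey boxplot summaries.

Anchoring convention: a break site is a single base coordinate (the
midpoint of the recognition interval, rounded down); a window of
half-width ``h`` covers bases ``[center - h, center + h)`` and is
truncated at chromosome ends (never dropped); mean statistics use the
truncated width and averaged profiles track per-offset denominators so
truncation does not bias them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoverageTrack

__all__ = [
    "CutUncutTest",
    "SignalMatrix",
    "AverageProfile",
    "MetageneProfile",
    "BoxplotSummary",
    "window_count",
    "quantify_sites",
    "compare_cut_uncut",
    "compare_paired",
    "stratify_by_transcription",
    "heatmap_matrix",
    "average_profile",
    "metagene_profile",
    "genes_near_dsb",
    "boxplot_summary",
]

FOUR_CLASS_LABELS = ("low", "medium_low", "medium_high", "high")


def _window_bounds(track: CoverageTrack, chrom: str, center: int,
                   halfwidth: int) -> tuple[np.ndarray, int, int]:
    if halfwidth <= 0:
        raise ValueError(f"halfwidth must be positive, got {halfwidth}")
    arr = track[chrom]  # KeyError -> informative message from CoverageTrack
    lo, hi = center - halfwidth, center + halfwidth
    if hi <= 0 or lo >= arr.size:
        raise ValueError(
            f"window [{lo}, {hi}) entirely off chromosome {chrom} "
            f"(length {arr.size})"
        )
    return arr, max(lo, 0), min(hi, arr.size)


def window_count(track: CoverageTrack, chrom: str, center: int,
                 halfwidth: int, statistic: str = "sum") -> float:
    """Sum or mean of coverage on ``[center - h, center + h)``.

    Truncated at chromosome ends; the mean divides by the truncated width.
    """
    arr, lo, hi = _window_bounds(track, chrom, center, halfwidth)
    seg = arr[lo:hi]
    if statistic == "sum":
        return float(seg.sum())
    if statistic == "mean":
        return float(seg.mean())
    raise ValueError(f"statistic must be 'sum' or 'mean', got {statistic!r}")


def _as_site_frame(sites) -> pd.DataFrame:
    df = pd.DataFrame(sites).copy()
    for col in ("site_id", "chrom", "position"):
        if col not in df.columns:
            raise ValueError(f"sites table missing column {col!r}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValueError(f"duplicate site id {dup!r}")
    return df


def quantify_sites(track: CoverageTrack, sites, halfwidth: int,
                   statistic: str = "sum", column: str = "signal") -> pd.DataFrame:
    """Windowed signal per site: one row per site id.

    ``sites`` is a DataFrame (or records) with at least site_id, chrom and
    position; cut flags and cleavage efficiencies are carried through.
    Returns a frame indexed by site_id with the window value in ``column``.
    """
    df = _as_site_frame(sites)
    if len(df) == 0:
        raise ValueError("empty site table")
    vals = []
    for s in df.itertuples():
        try:
            vals.append(window_count(track, s.chrom, int(s.position),
                                     halfwidth, statistic))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"site {s.site_id}: {exc}") from exc
    out = df.set_index("site_id")
    out[column] = vals
    out.attrs["window_halfwidth"] = halfwidth
    out.attrs["statistic"] = statistic
    return out


@dataclass
class CutUncutTest:
    """Two-sided Mann-Whitney U comparison of cut vs uncut site signals."""

    n_cut: int
    n_uncut: int
    statistic: float
    p_value: float
    direction: str  # "cut", "uncut" or "none": which group has the larger median
    method: str = "asymptotic"


def compare_cut_uncut(quants: pd.DataFrame, column: str = "signal") -> CutUncutTest:
    """Mann-Whitney U test of the window signal between cut and uncut sites.

    Exact enumeration when both groups have <= 8 sites and the pooled
    values are tie-free; normal approximation with tie correction
    otherwise.  The comparison is unpaired: cut and uncut are different
    site sets (a paired signed-rank variant for before/after at the same
    sites is :func:`compare_paired`).
    """
    if "cut" not in quants.columns:
        raise ValueError("quantification table has no 'cut' column")
    cut = quants.loc[quants["cut"].astype(bool), column].to_numpy(dtype=float)
    uncut = quants.loc[~quants["cut"].astype(bool), column].to_numpy(dtype=float)
    if len(cut) == 0 or len(uncut) == 0:
        raise ValueError(
            f"both groups must be non-empty (cut={len(cut)}, uncut={len(uncut)})"
        )
    pooled = np.concatenate([cut, uncut])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(cut) <= 8 and len(uncut) <= 8 and tie_free) \
        else "asymptotic"
    res = stats.mannwhitneyu(cut, uncut, alternative="two-sided", method=method)
    med_c, med_u = float(np.median(cut)), float(np.median(uncut))
    direction = "cut" if med_c > med_u else ("uncut" if med_u > med_c else "none")
    return CutUncutTest(n_cut=len(cut), n_uncut=len(uncut),
                        statistic=float(res.statistic),
                        p_value=float(min(res.pvalue, 1.0)),
                        direction=direction, method=method)


def compare_paired(before, after) -> tuple[float, float]:
    """Wilcoxon signed-rank test for the same sites in two conditions.

    Returns (statistic, two-sided p).  Use for -damage vs +damage at an
    identical site set; for different site sets use
    :func:`compare_cut_uncut`.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired comparison requires equal-length vectors")
    res = stats.wilcoxon(before, after, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def stratify_by_transcription(quants: pd.DataFrame, score_column: str,
                              n_classes: int = 4,
                              class_column: str = "transcription_class"
                              ) -> pd.DataFrame:
    """Split sites into ordered transcription classes of near-equal size.

    Sites are sorted by the score (ties broken by site id, ascending) and
    cut into ``n_classes`` contiguous groups ordered low -> high.  When the
    count is not divisible the lower classes take the extra sites, so sizes
    differ by at most one.  With four classes the labels are
    low / medium_low / medium_high / high.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if len(quants) < n_classes:
        raise ValueError(f"{len(quants)} sites cannot fill {n_classes} classes")
    score = pd.to_numeric(quants[score_column], errors="coerce")
    if score.isna().any():
        bad = quants.index[score.isna()][0]
        raise ValueError(f"non-numeric score for site {bad!r}")
    # stable sort: pre-sort by site id so ties break by id, then by score
    order = quants.assign(__score=score).sort_index(kind="mergesort") \
        .sort_values("__score", kind="mergesort")
    n = len(order)
    base, extra = divmod(n, n_classes)
    sizes = [base + (1 if i < extra else 0) for i in range(n_classes)]
    if n_classes == 4:
        labels = list(FOUR_CLASS_LABELS)
    else:
        labels = [f"class_{i + 1}" for i in range(n_classes)]
    assignment = np.repeat(labels, sizes)
    out = quants.copy()
    out[class_column] = pd.Categorical(
        pd.Series(assignment, index=order.index).reindex(out.index),
        categories=labels, ordered=True,
    )
    return out


@dataclass
class SignalMatrix:
    """Sites x fixed-width bins matrix of mean signal, for heatmaps."""

    site_ids: list[str]
    bin_edges: np.ndarray  # offsets from site center, length n_bins + 1
    matrix: np.ndarray     # (n_sites, n_bins) bin means; NaN where off-chromosome
    ordering_key: str
    bin_width: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{int(self.bin_edges[i])}:{int(self.bin_edges[i + 1])}"
                for i in range(len(self.bin_edges) - 1)]
        return pd.DataFrame(self.matrix, index=self.site_ids, columns=cols)


def heatmap_matrix(track: CoverageTrack, sites, halfwidth: int = 5000,
                   bin_width: int = 500, ordering: str = "cleavage_desc"
                   ) -> SignalMatrix:
    """Mean signal in fixed-width bins centered on each site.

    Rows are ordered by decreasing cleavage efficiency
    (``cleavage_desc``) or decreasing ``score`` column (``score_desc``),
    ties broken by site id.  For fully covered windows the bin means times
    the bin width sum exactly to the window sum.  Bins truncated by a
    chromosome end average over their covered bases; fully off-chromosome
    bins are NaN.
    """
    if (2 * halfwidth) % bin_width != 0:
        raise ValueError(
            f"window span {2 * halfwidth} not divisible by bin width {bin_width}"
        )
    df = _as_site_frame(sites)
    key_col = {"cleavage_desc": "cleavage_efficiency", "score_desc": "score"}.get(ordering)
    if key_col is None:
        raise ValueError(f"unknown ordering {ordering!r}")
    if key_col not in df.columns:
        raise ValueError(f"ordering {ordering!r} needs column {key_col!r}")
    df = df.sort_values(["site_id"]).sort_values(
        key_col, ascending=False, kind="mergesort"
    )
    n_bins = (2 * halfwidth) // bin_width
    edges = np.arange(n_bins + 1) * bin_width - halfwidth
    mat = np.full((len(df), n_bins), np.nan)
    for i, s in enumerate(df.itertuples()):
        arr = track[s.chrom]
        for b in range(n_bins):
            lo = int(s.position) + int(edges[b])
            hi = int(s.position) + int(edges[b + 1])
            lo_c, hi_c = max(lo, 0), min(hi, arr.size)
            if hi_c > lo_c:
                mat[i, b] = arr[lo_c:hi_c].mean()
    return SignalMatrix(site_ids=list(df["site_id"]), bin_edges=edges,
                        matrix=mat, ordering_key=ordering, bin_width=bin_width)


@dataclass
class AverageProfile:
    """Across-site mean signal by offset from the site center."""

    offsets: np.ndarray  # bin-center offsets from the site, bp
    mean: np.ndarray
    n: np.ndarray        # per-offset denominator (sites contributing)
    resolution: int


def average_profile(track: CoverageTrack, sites, halfwidth: int,
                    resolution: int = 1) -> AverageProfile:
    """Position-wise mean signal across sites on ``[-h, +h)``.

    ``resolution`` > 1 first averages each site's signal in bins of that
    width.  Sites whose window is truncated by a chromosome end contribute
    only their covered offsets; denominators are tracked per offset.
    """
    if (2 * halfwidth) % resolution != 0:
        raise ValueError(
            f"window span {2 * halfwidth} not divisible by resolution {resolution}"
        )
    df = _as_site_frame(sites)
    if len(df) == 0:
        raise ValueError("empty site table")
    n_bins = (2 * halfwidth) // resolution
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=int)
    for s in df.itertuples():
        arr = track[s.chrom]
        for b in range(n_bins):
            lo = int(s.position) - halfwidth + b * resolution
            hi = lo + resolution
            lo_c, hi_c = max(lo, 0), min(hi, arr.size)
            if hi_c > lo_c:
                total[b] += arr[lo_c:hi_c].mean()
                count[b] += 1
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    offsets = -halfwidth + (np.arange(n_bins) + 0.5) * resolution
    return AverageProfile(offsets=offsets, mean=mean, n=count,
                          resolution=resolution)


@dataclass
class MetageneProfile:
    """Mean coverage over genes rescaled to a common length.

    ``upstream``/``downstream`` are fixed-width flank bins (5' flank first;
    minus-strand genes are reversed so bin 1 is always 5'), ``body`` has a
    fixed bin count regardless of gene length.
    """

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_genes: int
    n_excluded: int
    flank_bin: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _bin_means(arr: np.ndarray, edges: list[tuple[int, int]]) -> np.ndarray:
    out = np.full(len(edges), np.nan)
    for i, (lo, hi) in enumerate(edges):
        lo_c, hi_c = max(lo, 0), min(hi, arr.size)
        if hi_c > lo_c:
            out[i] = arr[lo_c:hi_c].mean()
    return out


def metagene_profile(track: CoverageTrack, genes, flank: int = 3000,
                     flank_bin: int = 200, n_body_bins: int = 100,
                     length_weighted: bool = False) -> MetageneProfile:
    """Metagene profile: fixed-width flanks plus a scaled gene body.

    Mean coverage is computed in ``flank / flank_bin`` fixed-width bins on
    each flank and in ``n_body_bins`` equal fractions of the gene body
    (body bin ``b`` of a gene of length L covers bases
    ``[floor((b-1) L / n), floor(b L / n))``).  Genes shorter than
    ``n_body_bins`` are excluded (counted in ``n_excluded``).  Aggregation
    across genes is an unweighted mean by default; ``length_weighted``
    weights genes by length instead.
    """
    if flank % flank_bin != 0:
        raise ValueError(f"flank {flank} not divisible by flank_bin {flank_bin}")
    gdf = pd.DataFrame(genes)
    for col in ("chrom", "start", "end", "strand"):
        if col not in gdf.columns:
            raise ValueError(f"gene table missing column {col!r}")
    n_flank = flank // flank_bin
    rows, weights = [], []
    n_excluded = 0
    for g in gdf.itertuples():
        L = int(g.end) - int(g.start)
        if L < n_body_bins:
            n_excluded += 1
            continue
        arr = track[g.chrom]
        up_edges = [(int(g.start) - flank + i * flank_bin,
                     int(g.start) - flank + (i + 1) * flank_bin)
                    for i in range(n_flank)]
        body_edges = [(int(g.start) + (b * L) // n_body_bins,
                       int(g.start) + ((b + 1) * L) // n_body_bins)
                      for b in range(n_body_bins)]
        down_edges = [(int(g.end) + i * flank_bin,
                       int(g.end) + (i + 1) * flank_bin)
                      for i in range(n_flank)]
        up = _bin_means(arr, up_edges)
        body = _bin_means(arr, body_edges)
        down = _bin_means(arr, down_edges)
        if g.strand == "-":  # reverse so bin 1 is the 5' end
            up, body, down = down[::-1], body[::-1], up[::-1]
        rows.append(np.concatenate([up, body, down]))
        weights.append(L if length_weighted else 1.0)
    if not rows:
        raise ValueError("no gene long enough for the requested body bins")
    stack = np.vstack(rows)
    w = np.asarray(weights, dtype=float)
    mask = ~np.isnan(stack)
    wsum = (np.where(mask, stack, 0.0) * w[:, None]).sum(axis=0)
    wtot = (mask * w[:, None]).sum(axis=0)
    mean = np.where(wtot > 0, wsum / np.maximum(wtot, 1e-300), np.nan)
    return MetageneProfile(upstream=mean[:n_flank],
                           body=mean[n_flank:n_flank + n_body_bins],
                           downstream=mean[n_flank + n_body_bins:],
                           n_genes=len(rows), n_excluded=n_excluded,
                           flank_bin=flank_bin)


def genes_near_dsb(genes, sites, max_distance: int = 1000) -> pd.DataFrame:
    """Genes directly damaged by, or close to, a cut site.

    A gene is selected iff a *cut* site lies inside it, or the distance from
    the site to the nearest gene base is strictly less than
    ``max_distance``.  Uncut annotated sites are ignored.
    """
    gdf = pd.DataFrame(genes)
    sdf = pd.DataFrame(sites)
    cut = sdf[sdf["cut"].astype(bool)] if "cut" in sdf.columns else sdf
    keep = np.zeros(len(gdf), dtype=bool)
    for i, g in enumerate(gdf.itertuples()):
        for s in cut.itertuples():
            if s.chrom != g.chrom:
                continue
            p = int(s.position)
            if g.start <= p < g.end:
                keep[i] = True
                break
            dist = g.start - p if p < g.start else p - (g.end - 1)
            if dist < max_distance:
                keep[i] = True
                break
    return gdf[keep]


@dataclass
class BoxplotSummary:
    """Tukey five-number summary with fence-based outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    are the extreme data values inside the fences q1 - 1.5 IQR and
    q3 + 1.5 IQR; outliers lie strictly outside.
    """

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def boxplot_summary(values) -> BoxplotSummary:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no values to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
    return BoxplotSummary(median=float(med), q1=float(q1), q3=float(q3),
                          whisker_low=float(inside.min()),
                          whisker_high=float(inside.max()),
                          outliers=sorted(float(v) for v in outliers))
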