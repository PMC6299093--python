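"""DSB-proximal enrichment profiles from binned coverage tracks.

The pipeline mirrors a standard cut-versus-uncut DRIP-seq comparison around
nuclease-induced double-strand breaks: coverage counted in fixed 50-bp bins
is RPKM-normalized per condition, converted to a per-bin
``log2((cut + c) / (uncut + c))`` track, and aggregated around the
top-ranked cut sites into five absolute-distance windows
(0-0.5, 0.5-1, 1-1.5, 1.5-2, 2-2.5 kb, pooling the left and right side of
each break).  A bin contributes to a window only when at least 90% of the
bin lies inside the window's genomic footprint.  Per-site window means feed
boxplot summaries and one-sample Wilcoxon signed-rank tests against 0,
computed overall and separately for genic and nongenic sites.

All coordinates are 0-based half-open (BED/bedGraph convention); the cut
position is the 0-based coordinate of the break.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, FormatError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 50
DEFAULT_MIN_OVERLAP_FRAC = 0.9
DEFAULT_TOP_K = 50
_OVERLAP_TOL = 1e-9  # guards the >= comparison against float round-off


@dataclasses.dataclass
class BinTrack:
    """Fixed-width genomic bins with one value each.

    ``df`` has columns ``chrom, start, end, value``; bins are sorted and
    non-overlapping, ``end - start == bin_width`` except possibly the last
    bin of a chromosome.
    """

    df: pd.DataFrame
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        df = self.df.reset_index(drop=True)
        for col in ("chrom", "start", "end", "value"):
            if col not in df.columns:
                raise FormatError(f"BinTrack missing column {col!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]).any():
                raise FormatError(f"BinTrack: overlapping bins on {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def same_grid_as(self, other: "BinTrack") -> bool:
        if len(self) != len(other):
            return False
        return bool(
            (self.df["chrom"].to_numpy() == other.df["chrom"].to_numpy()).all()
            and (self.df["start"].to_numpy() == other.df["start"].to_numpy()).all()
            and (self.df["end"].to_numpy() == other.df["end"].to_numpy()).all()
        )

    def with_values(self, values: np.ndarray) -> "BinTrack":
        df = self.df.copy()
        df["value"] = values
        return BinTrack(df, self.bin_width)


@dataclasses.dataclass(frozen=True)
class DistanceInterval:
    """Half-open window [lower, upper) on absolute distance from the cut, bp."""

    label: str
    lower: int
    upper: int


def default_intervals() -> list[DistanceInterval]:
    """The five canonical windows tiling 0-2.5 kb around a break."""
    edges = [0, 500, 1000, 1500, 2000, 2500]
    return [
        DistanceInterval(f"{lo / 1000:g}-{hi / 1000:g}", lo, hi)
        for lo, hi in zip(edges[:-1], edges[1:])
    ]


def parse_intervals(spec: str) -> list[DistanceInterval]:
    """Parse ``"0:500,500:1000,..."`` into distance windows."""
    out = []
    for part in spec.split(","):
        lo, hi = (int(v) for v in part.split(":"))
        if hi <= lo:
            raise ParameterError(f"bad interval {part!r}")
        out.append(DistanceInterval(f"{lo / 1000:g}-{hi / 1000:g}", lo, hi))
    return out


# ---------------------------------------------------------------------------
# Track arithmetic
# ---------------------------------------------------------------------------


def normalize_track(raw: BinTrack, total_reads: float) -> BinTrack:
    """RPKM-normalize per-bin read counts.

    ``value' = count / ((bin_length/1000) * (total_reads/1e6))`` — reads per
    kilobase per million mapped reads, using each bin's actual length (equal
    to the bin width except possibly for a chromosome's last bin).
    """
    if total_reads <= 0:
        raise ParameterError("total_reads must be > 0")
    length_kb = (raw.df["end"] - raw.df["start"]).to_numpy(float) / 1000.0
    values = raw.df["value"].to_numpy(float) / (length_kb * (total_reads / 1e6))
    return raw.with_values(values)


def log2_ratio_track(cut: BinTrack, uncut: BinTrack, pseudocount: float = 1.0) -> BinTrack:
    """Per-bin ``log2((cut + c)/(uncut + c))`` on two identically binned tracks."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    if not cut.same_grid_as(uncut):
        first = _first_grid_mismatch(cut, uncut)
        raise AlignmentError(f"bin grids differ (first mismatch: {first})")
    # computed as a difference of logs so that swapping the two conditions
    # negates every bin value exactly (bitwise), not just to rounding
    values = np.log2(cut.df["value"].to_numpy(float) + pseudocount) - np.log2(
        uncut.df["value"].to_numpy(float) + pseudocount
    )
    return cut.with_values(values)


def _first_grid_mismatch(a: BinTrack, b: BinTrack) -> str:
    n = min(len(a), len(b))
    for i in range(n):
        ra, rb = a.df.iloc[i], b.df.iloc[i]
        if (ra["chrom"], ra["start"], ra["end"]) != (rb["chrom"], rb["start"], rb["end"]):
            return f"row {i}: {ra['chrom']}:{ra['start']}-{ra['end']} vs {rb['chrom']}:{rb['start']}-{rb['end']}"
    return f"track lengths {len(a)} vs {len(b)}"


# ---------------------------------------------------------------------------
# Cut sites
# ---------------------------------------------------------------------------


def select_top_sites(sites: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """The k sites with highest cleavage score.

    Ties at the boundary are broken by (chrom, position) lexicographic
    order, so the selection is deterministic.  Asking for more sites than
    exist returns the whole table with a warning.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > len(sites):
        logger.warning("requested top %d of %d sites; returning all", k, len(sites))
        k = len(sites)
    ordered = sites.sort_values(
        ["cleavage_score", "chrom", "position"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return ordered.head(k).reset_index(drop=True)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    """Read cut sites from BED6.

    Score column holds the cleavage rank score; the name column carries a
    ``genic``/``nongenic`` tag (optionally prefixed, e.g. ``site7|genic``).
    The cut position is the start coordinate for 1-bp features, otherwise
    the integer midpoint of the feature.
    """
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"{path}: BED line {i + 1} has fewer than 5 columns")
        chrom, start, end, name, score = fields[:5]
        start, end = int(start), int(end)
        pos = start if end - start <= 1 else start + (end - start) // 2
        tag = name.split("|")[-1].lower()
        genic = tag != "nongenic"
        site_id = name if "|" not in name else name.split("|")[0]
        rows.append(
            {"chrom": chrom, "position": pos, "cleavage_score": float(score),
             "genic": genic, "site_id": site_id}
        )
    df = pd.DataFrame(rows, columns=["chrom", "position", "cleavage_score", "genic", "site_id"])
    if df["site_id"].duplicated().any():
        df["site_id"] = [f"{sid}_{i}" for i, sid in enumerate(df["site_id"])]
    return df


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, r in sites.iterrows():
            tag = "genic" if r["genic"] else "nongenic"
            fh.write(
                f"{r['chrom']}\t{int(r['position'])}\t{int(r['position']) + 1}\t"
                f"{r['site_id']}|{tag}\t{r['cleavage_score']:.6g}\t.\n"
            )


def read_bedgraph(path: str | Path, bin_width: int | None = None) -> BinTrack:
    """Read a 4-column bedGraph (track/header/comment lines skipped)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}: bedGraph line {i + 1} has fewer than 4 columns")
        rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if bin_width is None:
        widths = df["end"] - df["start"]
        bin_width = int(widths.mode().iloc[0]) if len(widths) else DEFAULT_BIN_WIDTH
    return BinTrack(df, bin_width)


def write_bedgraph(track: BinTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.df.itertuples(index=False):
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:.10g}\n")


# ---------------------------------------------------------------------------
# Window assignment and aggregation
# ---------------------------------------------------------------------------


def assign_bins(
    track: BinTrack,
    sites: pd.DataFrame,
    intervals: Sequence[DistanceInterval] | None = None,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
) -> pd.DataFrame:
    """Assign track bins to per-site distance windows under the overlap rule.

    For a site at position ``p`` and window ``[lower, upper)`` the genomic
    footprint is ``[p - upper, p - lower) U [p + lower, p + upper)`` (both
    sides of the break pooled).  A bin is assigned iff its overlap with the
    footprint is at least ``min_overlap_frac * bin_width`` (>= comparison,
    so a 45-bp overlap of a 50-bp bin passes the default 90% rule exactly).
    Sites are treated independently: a bin may serve several sites, but for
    any one site it can satisfy the rule for at most one window whenever
    ``min_overlap_frac > 0.5`` — adjacent windows partition the footprint,
    so overlap fractions across windows sum to at most 1 (asserted).

    Returns a long DataFrame ``site_id, interval, chrom, start, end, value,
    overlap_bp``.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ParameterError("min_overlap_frac must be in (0, 1]")
    if intervals is None:
        intervals = default_intervals()
    need = min_overlap_frac * track.bin_width - _OVERLAP_TOL
    out = []
    by_chrom = {chrom: sub for chrom, sub in track.df.groupby("chrom", sort=False)}
    reach = max(iv.upper for iv in intervals) + track.bin_width
    for site in sites.itertuples(index=False):
        whole = by_chrom.get(site.chrom)
        if whole is None:
            continue
        pos = int(site.position)
        # restrict to bins that can possibly touch the footprint
        all_starts = whole["start"].to_numpy(np.int64)
        lo_i = int(np.searchsorted(all_starts, pos - reach - track.bin_width))
        hi_i = int(np.searchsorted(all_starts, pos + reach))
        sub = whole.iloc[lo_i:hi_i]
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        assigned_mask = np.zeros(len(sub), bool)
        for iv in intervals:
            ov = np.zeros(len(sub), np.int64)
            for lo, hi in ((pos - iv.upper, pos - iv.lower), (pos + iv.lower, pos + iv.upper)):
                ov += np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
            hit = ov >= need
            if min_overlap_frac > 0.5:
                assert not (hit & assigned_mask).any(), "bin assigned to two windows of one site"
                assigned_mask |= hit
            if hit.any():
                chunk = sub.loc[hit, ["chrom", "start", "end", "value"]].copy()
                chunk.insert(0, "interval", iv.label)
                chunk.insert(0, "site_id", site.site_id)
                chunk["overlap_bp"] = ov[hit]
                out.append(chunk)
    if not out:
        return pd.DataFrame(
            columns=["site_id", "interval", "chrom", "start", "end", "value", "overlap_bp"]
        )
    return pd.concat(out, ignore_index=True)


def site_interval_means(assignments: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of assigned bin values per (site, window).

    (site, window) pairs with zero assigned bins simply do not appear; the
    caller can count omissions against ``len(sites) * len(intervals)``.
    """
    if assignments.empty:
        return pd.DataFrame(columns=["site_id", "interval", "mean_log2", "n_bins"])
    g = assignments.groupby(["site_id", "interval"], sort=False)["value"]
    out = g.agg(mean_log2="mean", n_bins="count").reset_index()
    return out


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SignedRankResult:
    statistic: float  # W+ — the sum of ranks of positive differences
    p_value: float
    n_used: int  # non-zero differences entering the test
    method: str  # "exact" or "normal-approx"


def signed_rank_test(
    values: Sequence[float] | np.ndarray,
    mu: float = 0.0,
    alternative: str = "two-sided",
) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test of ``values`` against ``mu``.

    Zero differences are dropped (standard convention).  The null
    distribution is exact (full enumeration of the 2^n sign assignments)
    for n <= 25 without ties among the absolute differences, and a normal
    approximation with continuity correction otherwise.  With no non-zero
    differences the test is undefined and ``p_value`` is NaN.
    """
    d = np.asarray(values, float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignedRankResult(float("nan"), float("nan"), 0, "undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative=alternative,
        method=method,
    )
    return SignedRankResult(
        statistic=w_plus,
        p_value=float(res.pvalue),
        n_used=n,
        method="exact" if method == "exact" else "normal-approx",
    )


def stratify_and_test(
    enrichments: pd.DataFrame,
    sites: pd.DataFrame,
    intervals: Sequence[DistanceInterval] | None = None,
    *,
    min_sites: int = 5,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-window summaries and signed-rank p-values, overall and by stratum.

    For every window and stratum (``all``, ``genic``, ``nongenic``) the
    per-site window means are summarized (median, quartiles, n) and tested
    two-sided against 0 with the one-sample Wilcoxon signed-rank test.  The
    test is withheld (p NaN, ``tested`` False) for windows with fewer than
    ``min_sites`` contributing sites or with no non-zero site means.  With
    ``bonferroni`` the p-values are multiplied by the number of windows
    (capped at 1) within each stratum.
    """
    if intervals is None:
        intervals = default_intervals()
    merged = enrichments.merge(sites[["site_id", "genic"]], on="site_id", how="left")
    rows = []
    for stratum in ("all", "genic", "nongenic"):
        if stratum == "all":
            sub = merged
        else:
            sub = merged[merged["genic"] == (stratum == "genic")]
        for iv in intervals:
            vals = sub.loc[sub["interval"] == iv.label, "mean_log2"].to_numpy(float)
            row = {
                "stratum": stratum,
                "interval": iv.label,
                "n_sites": len(vals),
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "q1": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                "q3": float(np.percentile(vals, 75)) if len(vals) else np.nan,
            }
            if len(vals) >= min_sites and (vals != 0).any():
                res = signed_rank_test(vals)
                row.update(p_value=res.p_value, statistic=res.statistic,
                           method=res.method, tested=True)
            else:
                if len(vals):
                    logger.warning(
                        "signed-rank test withheld for %s/%s (n=%d)",
                        stratum, iv.label, len(vals),
                    )
                row.update(p_value=np.nan, statistic=np.nan, method="withheld", tested=False)
            rows.append(row)
    out = pd.DataFrame(rows)
    if bonferroni:
        m = len(intervals)
        out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
    return out


def drip_profile(
    cut: BinTrack,
    uncut: BinTrack,
    sites: pd.DataFrame,
    *,
    top_k: int = DEFAULT_TOP_K,
    intervals: Sequence[DistanceInterval] | None = None,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    pseudocount: float = 1.0,
    tracks_are_log2: bool = False,
    total_reads_cut: float | None = None,
    total_reads_uncut: float | None = None,
    bonferroni: bool = False,
) -> dict:
    """End-to-end window profile from count (or precomputed log2) tracks.

    Count tracks are RPKM-normalized using the given library sizes (the
    track totals by default) and combined into a log2 cut/uncut track; with
    ``tracks_are_log2`` the ``cut`` track is taken as the ratio track
    directly.  Returns the per-site means, the per-window summary table and
    the ratio track.
    """
    if tracks_are_log2:
        ratio = cut
    else:
        tot_c = total_reads_cut or float(cut.df["value"].sum())
        tot_u = total_reads_uncut or float(uncut.df["value"].sum())
        ratio = log2_ratio_track(
            normalize_track(cut, tot_c), normalize_track(uncut, tot_u), pseudocount
        )
    top = select_top_sites(sites, top_k)
    assignments = assign_bins(ratio, top, intervals, min_overlap_frac)
    means = site_interval_means(assignments)
    summary = stratify_and_test(means, top, intervals, bonferroni=bonferroni)
    return {
        "ratio_track": ratio,
        "sites": top,
        "assignments": assignments,
        "site_interval_means": means,
        "summary": summary,
    }
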