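"""ROSE-style super-enhancer calling from occupancy peaks.

Enriched regions (peaks with a reads-per-million signal) are stitched when
within 15 kb of each other, after excluding peaks that overlap a promoter
(2.5 kb upstream of a TSS, strand-aware). Stitched regions are ranked by
total signal; the rank-vs-signal curve is min-max scaled to the unit square
and regions past the geometric inflection — the point where the tangent to
the curve has slope 1 — are called super-enhancers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Interval, ValidationError

GAP_BP = 15_000
PROMOTER_UPSTREAM_BP = 2_500

PEAK_COLUMNS = ["chrom", "start", "end", "signal"]


def promoter_windows(
    tss_set: list[Interval], upstream_bp: int = PROMOTER_UPSTREAM_BP
) -> list[Interval]:
    """Strand-aware promoter intervals: [TSS - upstream, TSS] for + strand,
    mirrored for -; the TSS base itself is included."""
    windows = []
    for tss in tss_set:
        pos = tss.start if tss.strand != "-" else tss.end - 1
        if tss.strand == "-":
            start, end = pos, pos + upstream_bp + 1
        else:
            start, end = max(0, pos - upstream_bp), pos + 1
        windows.append(Interval(tss.chrom, start, end, name=tss.name, strand=tss.strand))
    return windows


def stitch_peaks(
    peaks: pd.DataFrame,
    tss_set: list[Interval] | None = None,
    gap_bp: int = GAP_BP,
    promoter_upstream_bp: int = PROMOTER_UPSTREAM_BP,
) -> pd.DataFrame:
    """Merge peaks within ``gap_bp`` (inclusive) after promoter exclusion.

    ``peaks`` needs columns chrom, start, end, signal. Merging is
    transitive, so a chain of nearby peaks forms one region even when its
    extremes are far apart. Region signal is the sum of component signals.
    Returns chrom, start, end, n_peaks, signal.
    """
    missing = set(PEAK_COLUMNS) - set(peaks.columns)
    if missing:
        raise ValidationError(f"peak table missing columns {sorted(missing)}")
    if (peaks["signal"] < 0).any():
        raise ValidationError("negative peak signal")
    df = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if tss_set:
        promoters = promoter_windows(tss_set, promoter_upstream_bp)
        keep = np.ones(len(df), dtype=bool)
        for i, row in df.iterrows():
            for pw in promoters:
                if pw.chrom == row["chrom"] and row["start"] < pw.end and pw.start < row["end"]:
                    keep[i] = False
                    break
        df = df[keep].reset_index(drop=True)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        current = None
        for _, peak in sub.iterrows():
            if current is not None and peak["start"] - current["end"] <= gap_bp:
                current["end"] = max(current["end"], int(peak["end"]))
                current["n_peaks"] += 1
                current["signal"] += float(peak["signal"])
            else:
                if current is not None:
                    rows.append(current)
                current = {
                    "chrom": chrom,
                    "start": int(peak["start"]),
                    "end": int(peak["end"]),
                    "n_peaks": 1,
                    "signal": float(peak["signal"]),
                }
        if current is not None:
            rows.append(current)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_peaks", "signal"])


def superenhancer_cutoff(signal: np.ndarray) -> float:
    """Signal value at the slope-1 tangent point of the scaled rank curve.

    Signals are sorted ascending and both axes min-max scaled to [0, 1];
    the tangent point minimises (scaled signal - scaled rank). Regions with
    signal strictly above the returned cutoff are super-enhancers.
    Conventions: a flat curve has no elbow (cutoff = max, so zero supers);
    a single region is always super (cutoff below it).
    """
    y = np.sort(np.asarray(signal, dtype=float))
    n = y.size
    if n == 0:
        raise ValidationError("no regions")
    if n == 1:
        return float(y[0]) - 1.0  # single region: super by convention
    lo, hi = y[0], y[-1]
    if hi == lo:
        return float(hi)  # degenerate flat curve: no supers
    x = np.arange(n) / (n - 1)
    ys = (y - lo) / (hi - lo)
    i_star = int(np.argmin(ys - x))
    return float(y[i_star])


def rank_and_call_super(regions: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rank stitched regions by signal (1 = strongest) and flag
    super-enhancers past the inflection point. Returns (table, cutoff)."""
    if regions.empty:
        out = regions.copy()
        out["rank"] = pd.Series(dtype=int)
        out["is_super"] = pd.Series(dtype=bool)
        return out, float("nan")
    out = regions.copy()
    cutoff = superenhancer_cutoff(out["signal"].to_numpy())
    out["rank"] = (
        out["signal"].rank(ascending=False, method="first").astype(int)
    )
    out["is_super"] = out["signal"] > cutoff
    return out.sort_values("rank").reset_index(drop=True), cutoff
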