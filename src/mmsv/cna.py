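"""Copy-number binning, cytogenetic classification and boundary proximity.

Copy number arrives as per-sample segments of log2(tumor/normal). Gains
and losses are called from length-weighted mean log2 over a region with
thresholds of >= +0.2 and <= -0.2. Cytogenetic summaries follow the
standard myeloma panel: del(1p), amp(1q), del(13), del(17p), and
hyperdiploidy, where hyperdiploidy requires concordant gains of both
control regions on at least 4 of the 8 eligible chromosomes
(3, 5, 7, 9, 11, 15, 19, 21 in the human genome).

Translocation breakpoints are also scored for proximity to copy-number
state-change boundaries: secondary (MYC-type) translocations typically abut
focal amplifications, so the distance from a breakpoint to the nearest
boundary where the gain/neutral/loss state flips is a mechanistic readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import Interval, TranslocationCall, ValidationError, warn

GAIN_THRESHOLD = 0.2
LOSS_THRESHOLD = -0.2
HD_MIN_CHROMS = 4


def bin_cna(
    seg_df: pd.DataFrame, bin_bp: int, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Length-weighted mean log2 per fixed-width bin for one sample.

    ``seg_df`` needs columns chrom, start, end, log2 (0-based half-open).
    Bins with no segment coverage are NaN. Returns chrom, start, end, log2.
    """
    frames = []
    for chrom, length in chrom_lengths.items():
        n_bins = math.ceil(length / bin_bp)
        weight = np.zeros(n_bins)
        total = np.zeros(n_bins)
        sub = seg_df[seg_df["chrom"] == chrom]
        for start, end, value in zip(sub["start"], sub["end"], sub["log2"]):
            b0 = int(start // bin_bp)
            b1 = int((min(end, length) - 1) // bin_bp)
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_bp)
                hi = min(end, (b + 1) * bin_bp, length)
                if hi > lo:
                    weight[b] += hi - lo
                    total[b] += (hi - lo) * value
        with np.errstate(invalid="ignore"):
            values = np.where(weight > 0, total / np.maximum(weight, 1), np.nan)
        starts = np.arange(n_bins) * bin_bp
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_bp, length),
                    "log2": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def region_mean(seg_df: pd.DataFrame, region: Interval) -> float:
    """Length-weighted mean log2 of segments over ``region``; NaN if uncovered."""
    sub = seg_df[seg_df["chrom"] == region.chrom]
    lo = np.maximum(sub["start"].to_numpy(), region.start)
    hi = np.minimum(sub["end"].to_numpy(), region.end)
    overlap = np.maximum(hi - lo, 0)
    if overlap.sum() == 0:
        return float("nan")
    return float(np.dot(overlap, sub["log2"].to_numpy()) / overlap.sum())


def call_region(
    seg_df: pd.DataFrame,
    region: Interval,
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
) -> str:
    """'gain' / 'neutral' / 'loss' from the region's mean log2 (>= / <= inclusive)."""
    mean = region_mean(seg_df, region)
    if math.isnan(mean):
        warn(f"no segment coverage in {region.chrom}:{region.start}-{region.end}; neutral")
        return "neutral"
    if mean >= gain_thr:
        return "gain"
    if mean <= loss_thr:
        return "loss"
    return "neutral"


def classify_hyperdiploidy(
    calls_by_chrom: dict[str, list[str]], min_chroms: int = HD_MIN_CHROMS
) -> bool:
    """Hyperdiploid iff >= ``min_chroms`` chromosomes have BOTH of their
    control regions called 'gain' (concordant gains)."""
    n_concordant = 0
    for chrom, region_calls in calls_by_chrom.items():
        if len(region_calls) != 2:
            raise ValidationError(
                f"{chrom}: expected exactly 2 hyperdiploidy regions, got {len(region_calls)}"
            )
        if all(c == "gain" for c in region_calls):
            n_concordant += 1
    return n_concordant >= min_chroms


#: Interval names recognised as the focal cytogenetic panel.
FOCAL_REGIONS = {"del(1p)": "loss", "amp(1q)": "gain", "del(13)": "loss", "del(17p)": "loss"}
HD_REGION_NAME = "HD"


@dataclass
class CytogeneticSummary:
    sample: str
    hyperdiploid: bool
    del_1p: bool
    amp_1q: bool
    del_13: bool
    del_17p: bool
    region_means: dict = field(default_factory=dict, repr=False)
    region_calls: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        return {
            "sample": self.sample,
            "hyperdiploid": self.hyperdiploid,
            "del(1p)": self.del_1p,
            "amp(1q)": self.amp_1q,
            "del(13)": self.del_13,
            "del(17p)": self.del_17p,
        }


def classify_common_cna(
    seg_df: pd.DataFrame,
    regions: list[Interval],
    sample: str = ".",
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
    hd_min_chroms: int = HD_MIN_CHROMS,
) -> CytogeneticSummary:
    """Per-sample cytogenetic summary from a region panel.

    ``regions`` carries the focal panel (interval names 'del(1p)',
    'amp(1q)', 'del(13)', 'del(17p)') and the hyperdiploidy control regions
    (name 'HD', two per eligible chromosome, grouped by interval chromosome).
    """
    region_means: dict[str, float] = {}
    region_calls: dict[str, str] = {}
    focal: dict[str, bool] = {name: False for name in FOCAL_REGIONS}
    hd_by_chrom: dict[str, list[str]] = {}
    for iv in regions:
        c = call_region(seg_df, iv, gain_thr, loss_thr)
        key = f"{iv.name}@{iv.chrom}:{iv.start}"
        region_means[key] = region_mean(seg_df, iv)
        region_calls[key] = c
        if iv.name in FOCAL_REGIONS:
            focal[iv.name] = c == FOCAL_REGIONS[iv.name]
        elif iv.name == HD_REGION_NAME:
            hd_by_chrom.setdefault(iv.chrom, []).append(c)
    hyperdiploid = bool(hd_by_chrom) and classify_hyperdiploidy(hd_by_chrom, hd_min_chroms)
    return CytogeneticSummary(
        sample=sample,
        hyperdiploid=hyperdiploid,
        del_1p=focal["del(1p)"],
        amp_1q=focal["amp(1q)"],
        del_13=focal["del(13)"],
        del_17p=focal["del(17p)"],
        region_means=region_means,
        region_calls=region_calls,
    )


def state_change_boundaries(
    seg_df: pd.DataFrame,
    chrom: str,
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
    max_segment_span: int | None = None,
) -> np.ndarray:
    """Positions on ``chrom`` where the gain/neutral/loss state changes.

    Uncovered gaps (including beyond the first/last segment) count as
    neutral, so the edge of a non-neutral segment is always a boundary.
    ``max_segment_span`` optionally restricts to boundaries of segments no
    longer than the cap (a focality restriction; off by default).
    """
    sub = seg_df[seg_df["chrom"] == chrom].sort_values("start")
    if sub.empty:
        return np.array([], dtype=int)

    def state(value):
        if value >= gain_thr:
            return "gain"
        if value <= loss_thr:
            return "loss"
        return "neutral"

    # Partition the chromosome into pieces (uncovered gaps are neutral,
    # zero span); a junction where the state flips is a boundary.
    pieces: list[tuple[int, str, int | None]] = []  # (start, state, span or None for gap)
    cursor = 0
    for start, end, value in zip(sub["start"], sub["end"], sub["log2"]):
        if start > cursor:
            pieces.append((cursor, "neutral", None))
        pieces.append((int(start), state(value), int(end - start)))
        cursor = int(end)
    pieces.append((cursor, "neutral", None))  # beyond the last segment

    boundaries = []
    for left, right in zip(pieces, pieces[1:]):
        if left[1] == right[1]:
            continue
        if max_segment_span is not None:
            # focality: at least one flank must be a non-neutral segment
            # no longer than the cap
            def focal(piece):
                _, st, span = piece
                return st != "neutral" and span is not None and span <= max_segment_span

            if not (focal(left) or focal(right)):
                continue
        boundaries.append(right[0])
    return np.unique(np.asarray(boundaries, dtype=int))


def breakpoint_boundary_proximity(
    call: TranslocationCall,
    seg_df: pd.DataFrame,
    max_dist: int = 10_000,
    end: str = "both",
    gain_thr: float = GAIN_THRESHOLD,
    loss_thr: float = LOSS_THRESHOLD,
    max_segment_span: int | None = None,
) -> tuple[bool, float]:
    """Whether a breakpoint lies within ``max_dist`` (inclusive) of a
    copy-number state-change boundary, and the nearest such distance.

    ``end`` selects which breakpoint end to score ('A', 'B', or 'both' for
    the minimum over ends). Returns (within, distance); distance is inf if
    the chromosome has no state change.
    """
    ends = {"A": [("A",)], "B": [("B",)], "both": [("A",), ("B",)]}[end]
    best = float("inf")
    for (which,) in ends:
        chrom, pos = (
            (call.chrom_a, call.pos_a) if which == "A" else (call.chrom_b, call.pos_b)
        )
        bounds = state_change_boundaries(
            seg_df, chrom, gain_thr, loss_thr, max_segment_span
        )
        if bounds.size:
            best = min(best, float(np.min(np.abs(bounds - pos))))
    return best <= max_dist, best


def cooccurrence_test(
    a: np.ndarray | pd.Series, b: np.ndarray | pd.Series
) -> tuple[np.ndarray, float, float]:
    """2x2 table, odds ratio (Haldane-corrected if a cell is 0) and
    two-sided Fisher exact p for two per-sample binary annotations."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("annotations must align sample-wise")
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds_ratio), float(p)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
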