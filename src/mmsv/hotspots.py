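"""Translocation hotspot discovery.

Recurrently translocated regions are found with a 1 Mb window advanced in
0.5 Mb steps along each chromosome; a window's frequency is the fraction of
cohort samples with at least one breakpoint end inside it. Windows at or
above a frequency floor (1% by default) that overlap or abut are stitched
into hotspot regions. Recurrent partner pairs are scored as the fraction of
samples with a call joining the 1 Mb neighbourhoods of two anchor loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Interval, TranslocationCall, ValidationError


@dataclass
class HotspotRegion:
    chrom: str
    start: int
    end: int
    count: int
    frequency: float
    median_vaf: float | None


@dataclass
class PartnerPair:
    anchor_a: Interval
    anchor_b: Interval
    count: int
    frequency: float
    median_vaf: float | None


def _n_windows(length: int, window_bp: int, step_bp: int) -> int:
    # final partial window retained; a chromosome shorter than one window
    # still gets a single (truncated) window
    return max(1, math.ceil((length - window_bp) / step_bp) + 1)


def window_sample_frequency(
    calls: list[TranslocationCall],
    chrom_lengths: dict[str, int],
    cohort_n: int,
    window_bp: int = 1_000_000,
    step_bp: int = 500_000,
) -> pd.DataFrame:
    """Distinct-sample count and frequency per sliding window.

    A sample with several breakpoints in one window contributes once.
    Returns a DataFrame with columns chrom, start, end, count, frequency.
    """
    if cohort_n <= 0:
        raise ValidationError("cohort size must be positive")
    samples_per_window: dict[str, list[set]] = {
        chrom: [set() for _ in range(_n_windows(L, window_bp, step_bp))]
        for chrom, L in chrom_lengths.items()
    }
    for call in calls:
        for chrom, pos in call.ends():
            if chrom not in samples_per_window:
                continue
            sets = samples_per_window[chrom]
            # windows with start in (pos - window, pos]
            k_max = min(pos // step_bp, len(sets) - 1)
            k_min = max(0, math.floor((pos - window_bp) / step_bp) + 1)
            for k in range(k_min, k_max + 1):
                sets[k].add(call.sample)
    rows = []
    for chrom, L in chrom_lengths.items():
        for k, samples in enumerate(samples_per_window[chrom]):
            start = k * step_bp
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + window_bp, L),
                    "count": len(samples),
                    "frequency": len(samples) / cohort_n,
                }
            )
    return pd.DataFrame(rows)


def _median_vaf(vafs: list[float]) -> float | None:
    return float(np.median(vafs)) if vafs else None


def _region_stats(
    calls: list[TranslocationCall], chrom: str, start: int, end: int, cohort_n: int
) -> tuple[int, float, float | None]:
    samples, vafs = set(), []
    for call in calls:
        hit = False
        for c, pos in call.ends():
            if c == chrom and start <= pos < end:
                hit = True
        if hit:
            samples.add(call.sample)
            if call.vaf is not None:
                vafs.append(call.vaf)
    return len(samples), len(samples) / cohort_n, _median_vaf(vafs)


def stitch_hotspots(
    grid: pd.DataFrame,
    calls: list[TranslocationCall],
    cohort_n: int,
    min_freq: float = 0.01,
) -> list[HotspotRegion]:
    """Merge overlapping qualifying windows (frequency >= ``min_freq``)
    into hotspot regions; region frequency and median VAF are recomputed
    over each merged interval.

    With the half-overlap tiling, neighbouring windows overlap, so a run of
    consecutive qualifying steps merges; windows that merely abut are two
    steps apart (a non-qualifying window lies between) and stay separate.
    """
    qualifying = grid[grid["frequency"] >= min_freq]
    regions: list[HotspotRegion] = []
    for chrom, sub in qualifying.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        merged: list[list[int]] = []
        for _, row in sub.iterrows():
            if merged and row["start"] < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], int(row["end"]))
            else:
                merged.append([int(row["start"]), int(row["end"])])
        for start, end in merged:
            count, freq, med = _region_stats(calls, chrom, start, end, cohort_n)
            regions.append(HotspotRegion(chrom, start, end, count, freq, med))
    return regions


def _near(chrom: str, pos: int, anchor: Interval, radius_bp: int) -> bool:
    return chrom == anchor.chrom and anchor.distance_to(pos) <= radius_bp


def recurrent_pair_frequency(
    calls: list[TranslocationCall],
    anchor_a: Interval,
    anchor_b: Interval,
    cohort_n: int,
    radius_bp: int = 1_000_000,
) -> PartnerPair:
    """Fraction of samples with a call joining the ``radius_bp``
    neighbourhoods of two anchors, with the median VAF of one
    best-supported call per sample (highest total_reads, then lowest
    coordinate)."""
    if cohort_n <= 0:
        raise ValidationError("cohort size must be positive")
    per_sample: dict[str, TranslocationCall] = {}
    for call in calls:
        ab = _near(call.chrom_a, call.pos_a, anchor_a, radius_bp) and _near(
            call.chrom_b, call.pos_b, anchor_b, radius_bp
        )
        ba = _near(call.chrom_a, call.pos_a, anchor_b, radius_bp) and _near(
            call.chrom_b, call.pos_b, anchor_a, radius_bp
        )
        if not (ab or ba):
            continue
        best = per_sample.get(call.sample)
        if best is None or _support_key(call) > _support_key(best):
            per_sample[call.sample] = call
    vafs = [c.vaf for c in per_sample.values() if c.vaf is not None]
    return PartnerPair(
        anchor_a=anchor_a,
        anchor_b=anchor_b,
        count=len(per_sample),
        frequency=len(per_sample) / cohort_n,
        median_vaf=_median_vaf(vafs),
    )


def _support_key(call: TranslocationCall):
    total = call.total_reads if call.total_reads is not None else -1
    # higher support wins; ties broken toward the lowest coordinate
    return (total, (-call.pos_a, -call.pos_b))
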