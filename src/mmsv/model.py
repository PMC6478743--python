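"""Core in-memory containers shared across the pipeline.

All coordinates are 0-based half-open (BED convention). Conversion from
1-based formats (VCF, SEG) happens only at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class ValidationError(ValueError):
    """An input violates a structural invariant (coordinates, schema, ...)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line = line


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally named and stranded."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to(self, pos: int) -> int:
        """Distance from ``pos`` to the nearest base of the interval (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


class AnnotationSet:
    """Named collections of intervals (CSR windows, VD region, blacklist, ...).

    Categories are unique labels; intervals within a category may overlap.
    """

    def __init__(self):
        self._categories: dict[str, list[Interval]] = {}
        self._trees: dict[str, dict[str, IntervalTree]] = {}

    @property
    def categories(self) -> list[str]:
        return list(self._categories)

    def add_category(self, label: str, intervals: Iterable[Interval], replace=False):
        if label in self._categories and not replace:
            raise ValidationError(f"duplicate annotation category {label!r}")
        self._categories[label] = list(intervals)
        self._trees.pop(label, None)
        return self

    def __contains__(self, label: str) -> bool:
        return label in self._categories

    def __getitem__(self, label: str) -> list[Interval]:
        return self._categories[label]

    def _tree(self, label: str) -> dict[str, IntervalTree]:
        if label not in self._trees:
            by_chrom: dict[str, IntervalTree] = {}
            for iv in self._categories[label]:
                by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            self._trees[label] = by_chrom
        return self._trees[label]

    def overlapping(self, label: str, chrom: str, start: int, end: int | None = None):
        """Intervals of ``label`` overlapping [start, end) (a point if end is None)."""
        if end is None:
            end = start + 1
        tree = self._tree(label).get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


@dataclass
class GenomeAssembly:
    """A set of named chromosome sequences with derived lengths."""

    sequences: dict[str, str]

    def __post_init__(self):
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), clipped at chromosome bounds (never wrapped)."""
        if chrom not in self.sequences:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        L = self.lengths[chrom]
        return self.sequences[chrom][max(0, start) : min(L, end)]


class MappabilityTrack:
    """Step-valued per-base mappability in [0, 1]; uncovered bases count as 0."""

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # steps: chrom -> (starts, ends, values), sorted, non-overlapping
        self.steps = steps
        for chrom, (starts, ends, values) in steps.items():
            if np.any(values < 0) or np.any(values > 1):
                raise ValidationError(f"mappability outside [0, 1] on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValidationError(f"overlapping mappability steps on {chrom}")

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over [start, end); bases without coverage are 0."""
        if end <= start:
            raise ValidationError("empty interval")
        if chrom not in self.steps:
            return 0.0
        starts, ends, values = self.steps[chrom]
        lo = np.minimum(np.maximum(starts, start), end)
        hi = np.minimum(np.maximum(ends, start), end)
        overlap = np.maximum(hi - lo, 0)
        return float(np.dot(overlap, values) / (end - start))


@dataclass
class TranslocationCall:
    """One inter-chromosomal breakpoint pair for one sample.

    VAF is the fraction of reads spanning the rearranged junction among all
    reads spanning the breakpoint; ~0.5 marks a clonal heterozygous event in
    a diploid region.
    """

    sample: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    strand_a: str = "."
    strand_b: str = "."
    spanning_reads: int | None = None
    total_reads: int | None = None
    name: str = "."
    filter_flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValidationError("negative breakpoint coordinate")
        if (
            self.spanning_reads is not None
            and self.total_reads is not None
            and self.spanning_reads > self.total_reads
        ):
            raise ValidationError(
                f"spanning_reads > total_reads for call {self.name} ({self.sample})"
            )

    @property
    def vaf(self) -> float | None:
        """spanning/total, or None when read support is absent or total is 0."""
        if not self.total_reads:
            return None
        return self.spanning_reads / self.total_reads

    def ends(self) -> Iterator[tuple[str, int]]:
        yield self.chrom_a, self.pos_a
        yield self.chrom_b, self.pos_b


class CNASegmentSet:
    """Per-sample copy-number segments as log2(tumor/normal) ratios.

    Backed by a DataFrame with columns sample, chrom, start, end, log2
    (0-based half-open). Segments must not overlap within a sample/chromosome.
    """

    COLUMNS = ["sample", "chrom", "start", "end", "log2"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"segment table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            raise ValidationError("segment with start < 0 or end <= start")
        if not np.isfinite(df["log2"]).all():
            raise ValidationError("non-finite log2 ratio")
        df = df.sort_values(["sample", "chrom", "start"], kind="stable")
        prev_end = df.groupby(["sample", "chrom"])["end"].shift()
        if (df["start"] < prev_end).any():
            bad = df[df["start"] < prev_end].iloc[0]
            raise ValidationError(
                "overlapping segments for sample "
                f"{bad['sample']} on {bad['chrom']} at {int(bad['start'])}"
            )
        self.df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]

    def __len__(self) -> int:
        return len(self.df)


def warn(msg: str):
    warnings.warn(msg, UserWarning, stacklevel=3)
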