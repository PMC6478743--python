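"""Readers and writers for the text formats the pipeline touches.

Internal convention is 0-based half-open everywhere. BEDPE, BED and bedGraph
are already 0-based; VCF breakends and SEG tables are 1-based and converted
here, at the boundary, and nowhere else.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    AnnotationSet,
    CNASegmentSet,
    GenomeAssembly,
    Interval,
    MappabilityTrack,
    ParseError,
    TranslocationCall,
    ValidationError,
    warn,
)

# Our BEDPE dialect: ten standard columns, then explicit read support.
BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "spanning_reads", "total_reads",
]


def _apply_alias(chrom: str, aliases: dict | None) -> str:
    return aliases.get(chrom, chrom) if aliases else chrom


def _check_chrom(chrom: str, assembly: GenomeAssembly | None, path, line):
    if assembly is not None and chrom not in assembly:
        raise ValidationError(f"{path}:{line}: unknown chromosome {chrom!r}")


def read_breakpoint_pairs(
    path,
    dialect: str = "bedpe",
    assembly: GenomeAssembly | None = None,
    aliases: dict | None = None,
) -> list[TranslocationCall]:
    """Read translocation calls from BEDPE or VCF breakend records.

    The BEDPE dialect requires explicit ``spanning_reads`` and
    ``total_reads`` columns (11 and 12); the BEDPE ``name`` column carries
    the sample identifier. VCF breakends are paired by MATEID; unpaired
    breakends are dropped with a warning.
    """
    if dialect == "bedpe":
        return _read_bedpe(path, assembly, aliases)
    if dialect == "vcf_bnd":
        return _read_vcf_bnd(path, assembly, aliases)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_bedpe(path, assembly, aliases) -> list[TranslocationCall]:
    calls = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"expected >=12 BEDPE columns, got {len(fields)}", path, lineno
                )
            try:
                s1, e1, s2, e2 = (int(fields[i]) for i in (1, 2, 4, 5))
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate ({exc})", path, lineno)
            if s1 < 0 or s2 < 0 or e1 <= s1 or e2 <= s2:
                raise ParseError("interval with start < 0 or start >= end", path, lineno)
            c1 = _apply_alias(fields[0], aliases)
            c2 = _apply_alias(fields[3], aliases)
            _check_chrom(c1, assembly, path, lineno)
            _check_chrom(c2, assembly, path, lineno)

            def _count(tok):
                if tok in (".", "", "NA"):
                    return None
                return int(tok)

            try:
                calls.append(
                    TranslocationCall(
                        sample=fields[6],
                        chrom_a=c1, pos_a=s1, chrom_b=c2, pos_b=s2,
                        strand_a=fields[8], strand_b=fields[9],
                        spanning_reads=_count(fields[10]),
                        total_reads=_count(fields[11]),
                        name=fields[7] if fields[7] != "." else ".",
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path, lineno)
    return calls


def _info(rec, key, default=None):
    # pysam raises (not returns default) for keys missing from the header
    try:
        return rec.info[key]
    except (KeyError, ValueError):
        return default


def _read_vcf_bnd(path, assembly, aliases) -> list[TranslocationCall]:
    import pysam

    records = {}
    with pysam.VariantFile(os.fspath(path)) as vf:
        sample_default = vf.header.samples[0] if len(vf.header.samples) else "unknown"
        for rec in vf:
            if _info(rec, "SVTYPE") != "BND":
                continue
            records[rec.id] = rec

    calls, seen = [], set()
    for rid, rec in records.items():
        if rid in seen:
            continue
        mate_id = _info(rec, "MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        mate = records.get(mate_id)
        if mate is None:
            warn(f"unpaired breakend {rid} dropped")
            continue
        seen.update({rid, mate_id})
        a, b = sorted(
            [rec, mate], key=lambda r: (r.chrom, r.pos)
        )
        chrom_a = _apply_alias(a.chrom, aliases)
        chrom_b = _apply_alias(b.chrom, aliases)
        _check_chrom(chrom_a, assembly, path, None)
        _check_chrom(chrom_b, assembly, path, None)
        sample = _info(a, "SAMPLE", sample_default)
        spanning = _info(a, "SPANNING_READS")
        total = _info(a, "TOTAL_READS")
        calls.append(
            TranslocationCall(
                sample=str(sample),
                chrom_a=chrom_a, pos_a=a.pos - 1,  # VCF is 1-based
                chrom_b=chrom_b, pos_b=b.pos - 1,
                spanning_reads=None if spanning is None else int(spanning),
                total_reads=None if total is None else int(total),
                name=str(a.id),
            )
        )
    return calls


def write_breakpoint_pairs(calls: Iterable[TranslocationCall], path):
    """Write calls in the BEDPE dialect read by :func:`read_breakpoint_pairs`."""
    with open(path, "w") as fh:
        for c in calls:
            fields = [
                c.chrom_a, c.pos_a, c.pos_a + 1, c.chrom_b, c.pos_b, c.pos_b + 1,
                c.sample, c.name, c.strand_a, c.strand_b,
                "." if c.spanning_reads is None else c.spanning_reads,
                "." if c.total_reads is None else c.total_reads,
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")
    return path


def read_interval_annotation(
    path, category: str = "intervals", aliases: dict | None = None
) -> list[Interval]:
    """Read a standard BED file (3-6 columns) into a list of intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected >=3 BED columns", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate ({exc})", path, lineno)
            try:
                intervals.append(
                    Interval(
                        chrom=_apply_alias(fields[0], aliases),
                        start=start,
                        end=end,
                        name=fields[3] if len(fields) > 3 else ".",
                        strand=fields[5] if len(fields) > 5 else ".",
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), path, lineno)
    return intervals


def write_intervals(intervals: Iterable[Interval], path):
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )
    return path


# Accepted header spellings for SEG-style tables (case-insensitive).
_SEG_ALIASES = {
    "sample": {"sample", "id", "sample_id"},
    "chrom": {"chrom", "chr", "chromosome"},
    "start": {"start", "loc.start", "loc_start"},
    "end": {"end", "loc.end", "loc_end"},
    "log2": {"log2", "seg.mean", "seg_mean", "log2_ratio"},
}


def read_cna_segments(path, aliases: dict | None = None) -> CNASegmentSet:
    """Read a SEG-style TSV (1-based inclusive) of log2 tumor/normal segments."""
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for canonical, spellings in _SEG_ALIASES.items():
        for col in df.columns:
            if col.lower() in spellings:
                rename[col] = canonical
                break
    df = df.rename(columns=rename)
    missing = set(_SEG_ALIASES) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: SEG table missing columns {sorted(missing)}")
    df["start"] = df["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    df["end"] = df["end"].astype(int)
    if aliases:
        df["chrom"] = df["chrom"].map(lambda c: aliases.get(c, c))
    return CNASegmentSet(df)


def write_cna_segments(segments: CNASegmentSet, path):
    out = segments.df.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)
    return path


def read_mappability(path, aliases: dict | None = None) -> MappabilityTrack:
    """Read a bedGraph of per-range mappability values in [0, 1]."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("expected 4 bedGraph columns", path, lineno)
            chrom = _apply_alias(fields[0], aliases)
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"bad bedGraph fields ({exc})", path, lineno)
            if start < 0 or end <= start:
                raise ParseError("invalid bedGraph interval", path, lineno)
            if not 0.0 <= value <= 1.0:
                raise ParseError(f"mappability {value} outside [0, 1]", path, lineno)
            rows.setdefault(chrom, []).append((start, end, value))
    steps = {}
    for chrom, triples in rows.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        values = np.array([t[2] for t in triples], dtype=float)
        steps[chrom] = (starts, ends, values)
    return MappabilityTrack(steps)


def write_mappability(track: MappabilityTrack, path):
    with open(path, "w") as fh:
        for chrom in sorted(track.steps):
            starts, ends, values = track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
    return path


def read_genome(path) -> GenomeAssembly:
    """Read a FASTA into memory; duplicate headers are rejected."""
    sequences: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in sequences:
                raise ValidationError(f"{path}: duplicate FASTA header {rec.id!r}")
            sequences[rec.id] = str(rec.seq).upper()
    return GenomeAssembly(sequences)


def write_genome(assembly: GenomeAssembly, path, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in assembly.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_table(records, path, **kwargs):
    """Write a DataFrame (or record list) as TSV, round-trippable by read_table."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, **kwargs)
    return path


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_peaks(path, aliases: dict | None = None) -> pd.DataFrame:
    """Read a BED+score peak file (score column 5 = signal, e.g. RPM)."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError("expected >=5 columns (BED + score)", path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
                signal = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"bad peak fields ({exc})", path, lineno)
            if start < 0 or end <= start:
                raise ParseError("invalid peak interval", path, lineno)
            if signal < 0:
                raise ParseError("negative peak signal", path, lineno)
            rows.append(
                {
                    "chrom": _apply_alias(fields[0], aliases),
                    "start": start,
                    "end": end,
                    "signal": signal,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal"])


def write_peaks(peaks: pd.DataFrame, path):
    with open(path, "w") as fh:
        for i, row in peaks.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                f"\tpeak{i}\t{row['signal']:g}\n"
            )
    return path


def build_annotation_set(**categories) -> AnnotationSet:
    """Assemble an :class:`AnnotationSet` from keyword interval lists."""
    ann = AnnotationSet()
    for label, intervals in categories.items():
        ann.add_category(label, intervals)
    return ann
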