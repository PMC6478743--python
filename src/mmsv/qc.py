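"""Post-caller translocation quality control and breakpoint classification.

Three filters are applied to candidate translocations, mirroring standard
practice for long-insert WGS structural-variant callsets:

* a flank-homology filter removing junctions whose two sides share >= 80%
  ungapped identity in any 100 bp window within 1 kb of the breakpoint
  (such junctions are overwhelmingly mapping artifacts between repeats);
* a mappability filter removing breakpoints whose 1 kb flanks average
  < 20% mappability;
* a user-supplied blacklist of regions with recurrent sequencing anomalies.

IgH breakpoints are classified by mechanism region: class switch
recombination (CSR) windows (each switch region extended +/- 2.5 kb), the
variable/diversity (VD) segment region, or extragenic. CSR breakpoints mark
germinal-center class-switch errors; extragenic sub-clonal breakpoints mark
later secondary events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    AnnotationSet,
    GenomeAssembly,
    MappabilityTrack,
    TranslocationCall,
    ValidationError,
    warn,
)

CSR_WINDOW_BP = 2500

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UndefinedVAFError(ValueError):
    """Raised when VAF is requested for a call with zero spanning coverage."""


def compute_vaf(spanning_reads: int, total_reads: int) -> float:
    """Fraction of breakpoint-spanning reads supporting the rearrangement."""
    if spanning_reads < 0 or total_reads < spanning_reads:
        raise ValidationError(
            f"require 0 <= spanning ({spanning_reads}) <= total ({total_reads})"
        )
    if total_reads == 0:
        raise UndefinedVAFError("no reads span the breakpoint; VAF undefined")
    return spanning_reads / total_reads


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def max_window_identity(seq_a: str, seq_b: str, window_bp: int = 100) -> float:
    """Maximum ungapped identity over all aligned window pairs of two sequences.

    Every offset pairing of a ``window_bp`` window of ``seq_a`` with one of
    ``seq_b`` is scored (an O(L^2) scan, organised by diagonal so each
    diagonal is a vectorised sliding-window sum). Strand is the caller's
    concern: pass the reverse complement for the opposite orientation.
    """
    a, b = _encode(seq_a), _encode(seq_b)
    la, lb = len(a), len(b)
    if la < window_bp or lb < window_bp:
        raise ValidationError(
            f"sequence shorter than window ({min(la, lb)} < {window_bp})"
        )
    best = 0
    # diagonal d aligns a[k] with b[k + d]
    for d in range(-(la - window_bp), lb - window_bp + 1):
        a0, b0 = max(0, -d), max(0, d)
        n = min(la - a0, lb - b0)
        if n < window_bp:
            continue
        eq = (a[a0 : a0 + n] == b[b0 : b0 + n]).astype(np.int32)
        cs = np.cumsum(eq)
        sums = cs[window_bp - 1 :].copy()
        sums[1:] -= cs[: n - window_bp]
        m = int(sums.max())
        if m > best:
            best = m
            if best == window_bp:
                break
    return best / window_bp


def breakpoint_flanks(
    call: TranslocationCall, genome: GenomeAssembly, flank_bp: int, side: str
) -> tuple[str, str]:
    """(left, right) flank sequences of one breakpoint end, clipped at chromosome ends."""
    chrom, pos = (call.chrom_a, call.pos_a) if side == "A" else (call.chrom_b, call.pos_b)
    return genome.fetch(chrom, pos - flank_bp, pos), genome.fetch(chrom, pos, pos + flank_bp)


def homology_flag(
    call: TranslocationCall,
    genome: GenomeAssembly,
    flank_bp: int = 1000,
    window_bp: int = 100,
    identity_threshold: float = 0.80,
) -> bool:
    """True if any 100 bp window of the side-A flanks matches a side-B window
    at >= ``identity_threshold`` identity, on either strand of side B."""
    flanks_a = [f for f in breakpoint_flanks(call, genome, flank_bp, "A") if f]
    flanks_b = [f for f in breakpoint_flanks(call, genome, flank_bp, "B") if f]
    if (
        not flanks_a
        or not flanks_b
        or max(map(len, flanks_a)) < window_bp
        or max(map(len, flanks_b)) < window_bp
    ):
        raise ValidationError("flank shorter than the scan window on one side")
    for fa in flanks_a:
        if len(fa) < window_bp:
            continue
        for fb in flanks_b:
            if len(fb) < window_bp:
                continue
            for oriented in (fb, reverse_complement(fb)):
                if max_window_identity(fa, oriented, window_bp) >= identity_threshold:
                    return True
    return False


def mappability_flag(
    call: TranslocationCall,
    track: MappabilityTrack,
    flank_bp: int = 1000,
    threshold: float = 0.20,
) -> bool:
    """True if either breakpoint end averages < ``threshold`` mappability
    over the 1 kb on either side of it (2 kb per end, evaluated per end)."""
    for chrom, pos in call.ends():
        start = max(0, pos - flank_bp)
        end = pos + flank_bp
        if track.mean(chrom, start, end) < threshold:
            return True
    return False


def blacklist_flag(call: TranslocationCall, blacklist: AnnotationSet, label="blacklist") -> bool:
    """True if either breakpoint position (not its flanks) falls in a blacklist interval."""
    if label not in blacklist:
        return False
    return any(blacklist.overlapping(label, chrom, pos) for chrom, pos in call.ends())


@dataclass
class QCResult:
    kept: list[TranslocationCall]
    removed: list[TranslocationCall]
    reasons: pd.DataFrame = field(repr=False, default=None)


def apply_qc(
    calls: list[TranslocationCall],
    genome: GenomeAssembly | None = None,
    track: MappabilityTrack | None = None,
    blacklist: AnnotationSet | None = None,
    flank_bp: int = 1000,
    window_bp: int = 100,
    identity_threshold: float = 0.80,
    mappability_threshold: float = 0.20,
) -> QCResult:
    """Apply the homology, mappability and blacklist filters.

    A call is removed iff at least one filter fires; kept + removed
    partition the input and each removed call carries its reasons in
    ``filter_flags``. Filters whose supporting data are not supplied are
    skipped. Calls with flanks too short to scan are kept, flagged
    ``unevaluable``.
    """
    kept, removed, rows = [], [], []
    for call in calls:
        flags = set()
        if genome is not None:
            try:
                if homology_flag(call, genome, flank_bp, window_bp, identity_threshold):
                    flags.add("homology")
            except ValidationError:
                warn(f"call {call.name} ({call.sample}): flank unevaluable for homology")
                call.filter_flags.add("unevaluable")
        if track is not None and mappability_flag(call, track, flank_bp, mappability_threshold):
            flags.add("low_mappability")
        if blacklist is not None and blacklist_flag(call, blacklist):
            flags.add("blacklist")
        call.filter_flags |= flags
        if flags:
            removed.append(call)
            rows.append(
                {"sample": call.sample, "name": call.name,
                 "reasons": ",".join(sorted(flags))}
            )
        else:
            kept.append(call)
    return QCResult(kept=kept, removed=removed, reasons=pd.DataFrame(rows))


def annotate_vaf(calls: list[TranslocationCall]) -> list[TranslocationCall]:
    """Warn about calls whose VAF is undefined (zero spanning coverage)."""
    for call in calls:
        if call.total_reads == 0:
            warn(f"call {call.name} ({call.sample}) has zero coverage; VAF absent")
    return calls


def classify_breakpoint(
    chrom: str,
    pos: int,
    annotation: AnnotationSet,
    csr_label: str = "csr",
    vd_label: str = "vd",
    csr_window_bp: int = CSR_WINDOW_BP,
) -> str:
    """Classify a breakpoint as 'CSR', 'VD' or 'extragenic'.

    CSR membership means within ``csr_window_bp`` of a switch region (the
    +/- 2.5 kb windows); CSR takes precedence over VD where the extended
    windows overlap. Every position gets exactly one class.
    """
    if csr_label in annotation:
        for iv in annotation[csr_label]:
            if iv.chrom == chrom and iv.start - csr_window_bp <= pos < iv.end + csr_window_bp:
                return "CSR"
    if vd_label in annotation:
        if annotation.overlapping(vd_label, chrom, pos):
            return "VD"
    return "extragenic"


def breakpoint_bias_odds_ratio(table: np.ndarray | list) -> tuple[float, float]:
    """Odds ratio (Haldane-Anscombe corrected when a cell is 0) and
    two-sided Fisher exact p for a 2x2 translocation-type x region table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("expected a 2x2 table of non-negative integer counts")
    a, b, c, d = t.ravel()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(odds_ratio), float(p)
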