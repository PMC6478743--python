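"""Seeded synthetic myeloma cohort generator.

Emits every input the pipeline consumes — toy genome, annotations,
translocation calls with read support, copy-number segments, survival and
expression tables, mappability, blacklist, occupancy peaks — together with
a machine-readable truth record, so each detector can be scored exactly
without access to patient data.

The generator emulates the statistical structure of a newly-diagnosed
myeloma WGS cohort:

* clonal IgH translocations (VAF centred near 0.48) concentrated at class
  switch regions, partnered mostly with CCND1/WHSC1;
* sub-clonal MYC translocations (VAF centred near 0.26) whose breakpoints
  abut focal amplification boundaries in 85% of events, partnered with the
  immunoglobulin loci and other recurrent regions;
* IgL translocations in ~10% of samples, 41% of them IgL-MYC, with focal
  IgL-enhancer amplifications in 68% and strong co-occurrence with
  hyperdiploidy;
* hyperdiploid copy-number profiles (whole-chromosome gains of >= 4 of the
  8 eligible toy chromosomes) plus the del(1p)/amp(1q)/del(13)/del(17p)
  focal panel;
* exponential survival with planted log-hazard effects, including an
  IMiD-by-t(IgL) interaction in which the IMiD benefit applies only to
  non-t(IgL) patients, and ~30% independent censoring;
* a planted fraction of artifactual calls (homologous flanks, blacklist,
  low mappability) for the QC filters to remove;
* isotype/light-chain expression values and peak-signal curves with a
  planted super-enhancer elbow.

The toy genome has 12 chromosomes: four carrying the anchored loci (IgH,
MYC, IgL, IgK) and eight eligible for hyperdiploid whole-chromosome gain —
mirroring the real genome, where the MYC and immunoglobulin chromosomes
are not among the odd-numbered hyperdiploidy chromosomes. Keeping them
apart also keeps whole-chromosome gain boundaries away from the MYC locus.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .model import (
    AnnotationSet,
    CNASegmentSet,
    GenomeAssembly,
    Interval,
    MappabilityTrack,
    TranslocationCall,
    ValidationError,
)

LOCUS_CHROMS = ["chr1", "chr2", "chr3", "chr4"]
HD_CHROMS = [f"chr{i}" for i in range(5, 13)]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomeSpec:
    """Geography of the toy genome: chromosome lengths and locus placements."""

    chrom_lengths: dict[str, int]
    igh: Interval
    vd: Interval
    csr: list[Interval]
    anchors: dict[str, Interval]
    table1: list[Interval]
    blacklist: list[Interval]
    low_mappability: list[Interval]


def make_genome_spec(
    locus_chrom_len: int = 6_000_000, hd_chrom_len: int = 5_000_000
) -> GenomeSpec:
    L, H = locus_chrom_len, hd_chrom_len
    if L < 1_500_000 or H < 1_200_000:
        raise ValidationError("chromosomes too short to host the locus layout")
    lengths = {c: L for c in LOCUS_CHROMS} | {c: H for c in HD_CHROMS}
    igh = Interval("chr1", int(0.70 * L), int(0.80 * L), "IgH")
    vd = Interval("chr1", int(0.70 * L), int(0.745 * L), "VD")
    csr_base = int(0.755 * L)
    csr = [
        Interval("chr1", csr_base + k * 12_000, csr_base + k * 12_000 + 2_000, name)
        for k, name in enumerate(["S_M", "S_G3", "S_G1", "S_A1", "S_G2", "S_A2"])
    ]
    anchors = {
        "IgH": igh,
        "MYC": Interval("chr2", int(0.50 * L), int(0.50 * L) + 10_000, "MYC"),
        "IgL": Interval("chr3", int(0.50 * L), int(0.52 * L), "IgL"),
        "IgK": Interval("chr4", int(0.50 * L), int(0.52 * L), "IgK"),
        "CCND1": Interval("chr5", int(0.40 * H), int(0.40 * H) + 10_000, "CCND1"),
        "WHSC1": Interval("chr6", int(0.40 * H), int(0.40 * H) + 10_000, "WHSC1"),
        "TXNDC5": Interval("chr7", int(0.40 * H), int(0.40 * H) + 10_000, "TXNDC5"),
        "MAP3K14": Interval("chr8", int(0.40 * H), int(0.40 * H) + 10_000, "MAP3K14"),
    }
    table1 = [
        Interval("chr1", int(0.13 * L), int(0.16 * L), "del(1p)"),
        Interval("chr1", int(0.30 * L), int(0.33 * L), "amp(1q)"),
        Interval("chr3", int(0.17 * L), int(0.20 * L), "del(13)"),
        Interval("chr4", int(0.17 * L), int(0.20 * L), "del(17p)"),
    ]
    for chrom in HD_CHROMS:
        table1.append(Interval(chrom, int(0.10 * H), int(0.12 * H), "HD"))
        table1.append(Interval(chrom, int(0.80 * H), int(0.82 * H), "HD"))
    blacklist = [
        Interval("chr9", int(0.50 * H), int(0.51 * H), "bl1"),
        Interval("chr10", int(0.30 * H), int(0.31 * H), "bl2"),
        Interval("chr11", int(0.62 * H), int(0.63 * H), "bl3"),
    ]
    low_mappability = [
        Interval("chr9", int(0.80 * H), int(0.80 * H) + 6_000, "lm1"),
        Interval("chr12", int(0.30 * H), int(0.30 * H) + 6_000, "lm2"),
        Interval("chr12", int(0.70 * H), int(0.70 * H) + 6_000, "lm3"),
    ]
    return GenomeSpec(
        chrom_lengths=lengths,
        igh=igh,
        vd=vd,
        csr=csr,
        anchors=anchors,
        table1=table1,
        blacklist=blacklist,
        low_mappability=low_mappability,
    )


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort (defaults mirror the
    printed statistics of the newly-diagnosed CoMMpass cohort)."""

    n_samples: int = 795
    locus_chrom_len: int = 6_000_000
    hd_chrom_len: int = 5_000_000

    # translocation prevalences and partner repertoires
    p_t_igh: float = 0.41
    igh_partner_weights: dict = field(
        default_factory=lambda: {"CCND1": 0.45, "WHSC1": 0.30, "random": 0.25}
    )
    p_igh_csr: float = 0.75
    p_igh_vd: float = 0.10
    p_t_myc: float = 0.23
    myc_partner_weights: dict = field(
        default_factory=lambda: {
            "IgL": 0.176, "IgH": 0.165, "TXNDC5": 0.104, "IgK": 0.088, "random": 0.467,
        }
    )
    p_t_igl_other: float = 0.06

    # clonality (VAF) laws and read depth
    clonal_vaf_mean: float = 0.48
    clonal_vaf_concentration: float = 50.0
    subclonal_vaf_mean: float = 0.26
    subclonal_vaf_concentration: float = 25.0
    read_depth: float = 40.0

    # copy number
    myc_boundary_adjacent_frac: float = 0.85
    igl_amp_frac: float = 0.68
    p_hd_base: float = 0.60
    p_hd_clonal_igh: float = 0.15
    p_hd_igl_myc: float = 0.78
    hd_gain_log2: float = 0.45  # trisomy at high tumor purity
    focal_amp_log2: float = 0.5
    focal_del_log2: float = -0.5
    amp_1q_log2: float = 0.4
    p_amp_1q: float = 0.30
    p_del_13: float = 0.35
    p_del_17p: float = 0.10
    p_del_1p: float = 0.20
    cna_noise_sd: float = 0.05

    # artifacts for QC (fraction of genuine calls added as artifacts)
    artifact_rate: float = 0.10
    artifact_reason_weights: dict = field(
        default_factory=lambda: {"homology": 0.70, "blacklist": 0.15, "low_mappability": 0.15}
    )

    # survival
    baseline_hazard: float = 0.25  # events per year
    hr_t_igl: float = 2.0
    hr_imid_non_igl: float = 0.6  # IMiD benefit applies only to non-t(IgL)
    hr_amp_1q: float = 1.4
    hr_hd: float = 0.8
    hr_per_sv: float = 1.02
    p_imid: float = 0.73
    censoring_frac: float = 0.30

    # expression
    kappa_frac: float = 2 / 3
    isotype_weights: dict = field(
        default_factory=lambda: {
            "IGHG1": 0.40, "IGHA1": 0.15, "IGHM": 0.10, "IGHG2": 0.08,
            "IGHG3": 0.05, "IGHA2": 0.04, "none": 0.18,
        }
    )

    # peaks / super-enhancers
    n_background_peaks: int = 360
    n_promoter_peaks: int = 25
    n_super: int = 12
    n_tss: int = 160

    def genome_spec(self) -> GenomeSpec:
        return make_genome_spec(self.locus_chrom_len, self.hd_chrom_len)


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _weighted_choice(rng, weights: dict[str, float]) -> str:
    names = list(weights)
    p = np.array([weights[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=p / p.sum())]


class SyntheticCohort:
    """A fully generated cohort plus truth; genome sequence built lazily."""

    def __init__(self, config: CohortConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.spec = config.genome_spec()
        self._genome: GenomeAssembly | None = None
        ss = np.random.SeedSequence([self.seed, 20_19])
        self._genome_seed, events_seed, peaks_seed = ss.spawn(3)
        rng = np.random.default_rng(events_seed)
        self._simulate_samples(rng)
        self._simulate_peaks(np.random.default_rng(peaks_seed))

    # ------------------------------------------------------------------ events
    def _simulate_samples(self, rng):
        cfg, spec = self.config, self.spec
        self.calls: list[TranslocationCall] = []
        self.truth: dict = {"seed": self.seed, "samples": [], "config": _config_digest(cfg)}
        seg_rows = []
        surv_rows = []
        expr_rows = []
        self._homology_patches: list[tuple[str, int, str, int, np.ndarray]] = []

        clon_a, clon_b = _beta_params(cfg.clonal_vaf_mean, cfg.clonal_vaf_concentration)
        sub_a, sub_b = _beta_params(cfg.subclonal_vaf_mean, cfg.subclonal_vaf_concentration)

        genuine_calls = 0
        pending_artifact_sources = []
        for i in range(cfg.n_samples):
            sample = f"S{i:04d}"
            events = []
            focal_plan: dict[str, list[tuple[int, int, float]]] = {}

            # --- IgH-type clonal translocations
            t_igh = rng.random() < cfg.p_t_igh
            igh_partner = None
            if t_igh:
                igh_partner = _weighted_choice(rng, cfg.igh_partner_weights)
                region = self._draw_igh_region(rng)
                pos_a = self._draw_igh_breakpoint(rng, region)
                chrom_b, pos_b = self._draw_partner(rng, igh_partner)
                events.append(
                    dict(kind="igh", partner=igh_partner, region=region,
                         chrom_a="chr1", pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
                         clonal=True)
                )

            # --- MYC-type sub-clonal translocations (incl. IgH-MYC, IgL-MYC)
            t_myc = rng.random() < cfg.p_t_myc
            myc_partner = None
            adjacent = None
            if t_myc:
                myc_partner = _weighted_choice(rng, cfg.myc_partner_weights)
                pos_a = self._draw_myc_breakpoint(rng)
                chrom_b, pos_b = self._draw_partner(rng, myc_partner)
                adjacent = bool(rng.random() < cfg.myc_boundary_adjacent_frac)
                distance = None
                if adjacent:
                    distance = int(rng.integers(0, 10_001))
                    focal_plan.setdefault("chr2", []).append(
                        self._amp_near(rng, "chr2", pos_a, distance)
                    )
                events.append(
                    dict(kind="myc", partner=myc_partner,
                         chrom_a="chr2", pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
                         clonal=False, adjacent=adjacent, boundary_distance=distance)
                )

            # --- other IgL translocations
            t_igl_other = rng.random() < cfg.p_t_igl_other
            if t_igl_other:
                partner = "MAP3K14" if rng.random() < 0.4 else "random"
                pos_a = self._draw_light_chain_breakpoint(rng, "IgL")
                chrom_b, pos_b = self._draw_partner(rng, partner)
                events.append(
                    dict(kind="igl_other", partner=partner,
                         chrom_a="chr3", pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
                         clonal=False)
                )

            igl_myc = t_myc and myc_partner == "IgL"
            t_igl = igl_myc or t_igl_other

            # IgL 3' enhancer amplification accompanies most t(IgL)
            igl_amp = t_igl and rng.random() < cfg.igl_amp_frac
            if igl_amp:
                igl = spec.anchors["IgL"]
                length = int(rng.integers(60_000, 250_000))
                start = igl.end - int(rng.integers(0, 20_000))
                focal_plan.setdefault("chr3", []).append(
                    (start, start + length, cfg.focal_amp_log2)
                )

            # --- hyperdiploidy and the focal CNA panel
            clonal_igh = t_igh and igh_partner in ("CCND1", "WHSC1")
            if igl_myc:
                p_hd = cfg.p_hd_igl_myc
            elif clonal_igh:
                p_hd = cfg.p_hd_clonal_igh
            else:
                p_hd = cfg.p_hd_base
            hd = bool(rng.random() < p_hd)
            if hd:
                k = int(rng.integers(4, len(HD_CHROMS) + 1))
            else:
                k = int(rng.integers(0, 4))  # sporadic gains below the threshold
            gained = set(rng.choice(HD_CHROMS, size=k, replace=False)) if k else set()

            focal_truth = {}
            for flag_name, region_name, p, value in [
                ("amp_1q", "amp(1q)", cfg.p_amp_1q, cfg.amp_1q_log2),
                ("del_1p", "del(1p)", cfg.p_del_1p, cfg.focal_del_log2),
                ("del_13", "del(13)", cfg.p_del_13, cfg.focal_del_log2),
                ("del_17p", "del(17p)", cfg.p_del_17p, cfg.focal_del_log2),
            ]:
                present = bool(rng.random() < p)
                focal_truth[flag_name] = present
                if present:
                    region = next(r for r in spec.table1 if r.name == region_name)
                    pad = int(rng.integers(0, 50_000))
                    focal_plan.setdefault(region.chrom, []).append(
                        (max(0, region.start - pad), region.end + pad, value)
                    )

            seg_rows.extend(self._build_segments(rng, sample, gained, focal_plan))

            # --- emit genuine calls (binomial read support)
            for k_ev, ev in enumerate(events):
                a, b = (clon_a, clon_b) if ev["clonal"] else (sub_a, sub_b)
                vaf_true = float(rng.beta(a, b))
                total = max(1, int(rng.poisson(cfg.read_depth)))
                spanning = int(rng.binomial(total, vaf_true))
                call = TranslocationCall(
                    sample=sample,
                    chrom_a=ev["chrom_a"], pos_a=ev["pos_a"],
                    chrom_b=ev["chrom_b"], pos_b=ev["pos_b"],
                    strand_a="+", strand_b="-",
                    spanning_reads=spanning, total_reads=total,
                    name=f"{sample}_e{k_ev}",
                )
                ev["vaf_true"] = vaf_true
                ev["call_name"] = call.name
                self.calls.append(call)
                genuine_calls += 1
            pending_artifact_sources.append(sample)

            # --- survival
            n_sv = len(events) + int(rng.poisson(18))
            imid = bool(rng.random() < cfg.p_imid)
            log_h = (
                np.log(cfg.baseline_hazard)
                + np.log(cfg.hr_t_igl) * t_igl
                + np.log(cfg.hr_imid_non_igl) * (imid and not t_igl)
                + np.log(cfg.hr_amp_1q) * focal_truth["amp_1q"]
                + np.log(cfg.hr_hd) * hd
                + np.log(cfg.hr_per_sv) * n_sv
            )
            h = float(np.exp(log_h))
            t_event = float(rng.exponential(1.0 / h))
            c = cfg.censoring_frac
            t_censor = float(rng.exponential((1 - c) / (c * h)))
            surv_rows.append(
                {
                    "sample": sample,
                    "time": min(t_event, t_censor),
                    "event": int(t_event <= t_censor),
                    "t_igl": int(t_igl),
                    "imid": int(imid),
                    "amp_1q": int(focal_truth["amp_1q"]),
                    "hd": int(hd),
                    "n_sv": n_sv,
                }
            )

            # --- expression
            expr_rows.append(self._draw_expression(rng, sample))

            self.truth["samples"].append(
                {
                    "sample": sample,
                    "t_igh": t_igh,
                    "t_myc": t_myc,
                    "t_igl": t_igl,
                    "igl_myc": igl_myc,
                    "igl_amp": igl_amp,
                    "hd": hd,
                    "gained_chroms": sorted(gained),
                    **focal_truth,
                    "events": events,
                    "artifacts": [],
                }
            )

        # --- artifactual calls for the QC filters
        n_art = int(round(cfg.artifact_rate * genuine_calls))
        art_samples = rng.choice(pending_artifact_sources, size=n_art) if n_art else []
        by_sample = {s["sample"]: s for s in self.truth["samples"]}
        for j, sample in enumerate(art_samples):
            reason = _weighted_choice(rng, cfg.artifact_reason_weights)
            call = self._make_artifact(rng, str(sample), f"{sample}_a{j}", reason)
            self.calls.append(call)
            by_sample[str(sample)]["artifacts"].append(
                {"call_name": call.name, "reason": reason}
            )

        self.segments = CNASegmentSet(pd.DataFrame(seg_rows))
        self.survival = pd.DataFrame(surv_rows)
        self.expression = pd.DataFrame(expr_rows).set_index("sample")
        self.truth["survival_model"] = {
            "hr_t_igl": cfg.hr_t_igl,
            "hr_imid_non_igl": cfg.hr_imid_non_igl,
            "hr_amp_1q": cfg.hr_amp_1q,
            "hr_hd": cfg.hr_hd,
            "hr_per_sv": cfg.hr_per_sv,
        }
        self.mappability = self._build_mappability()

    # ------------------------------------------------------------- draw helpers
    def _draw_igh_region(self, rng) -> str:
        cfg = self.config
        u = rng.random()
        if u < cfg.p_igh_csr:
            return "CSR"
        if u < cfg.p_igh_csr + cfg.p_igh_vd:
            return "VD"
        return "extragenic"

    def _draw_igh_breakpoint(self, rng, region: str) -> int:
        spec = self.spec
        if region == "CSR":
            sw = spec.csr[rng.integers(0, len(spec.csr))]
            return int(rng.integers(sw.start, sw.end))
        if region == "VD":
            return int(rng.integers(spec.vd.start, spec.vd.end))
        lo = spec.igh.start - 100_000
        hi = spec.igh.end + 100_000
        while True:
            pos = int(rng.integers(lo, hi))
            in_vd = spec.vd.start <= pos < spec.vd.end
            in_csr = any(s.start - 2_500 <= pos < s.end + 2_500 for s in spec.csr)
            if not in_vd and not in_csr:
                return pos

    def _draw_myc_breakpoint(self, rng) -> int:
        myc = self.spec.anchors["MYC"]
        if rng.random() < 0.6:
            return int(rng.integers(myc.start - 30_000, myc.end + 30_000))
        # second cluster telomeric of the locus (PVT1-like)
        return int(rng.integers(myc.start + 570_000, myc.start + 630_000))

    def _draw_light_chain_breakpoint(self, rng, which: str) -> int:
        locus = self.spec.anchors[which]
        # clustered at the 3' joining/constant end
        return int(rng.integers(locus.end - 20_000, locus.end + 10_000))

    def _draw_partner(self, rng, partner: str) -> tuple[str, int]:
        spec = self.spec
        if partner == "IgL" or partner == "IgK":
            return spec.anchors[partner].chrom, self._draw_light_chain_breakpoint(rng, partner)
        if partner == "IgH":
            region = self._draw_igh_region(rng)
            return "chr1", self._draw_igh_breakpoint(rng, region)
        if partner in spec.anchors:
            iv = spec.anchors[partner]
            return iv.chrom, int(rng.integers(iv.start - 50_000, iv.end + 50_000))
        return self._draw_random_position(rng)

    def _draw_random_position(self, rng) -> tuple[str, int]:
        spec = self.spec
        chroms = list(spec.chrom_lengths)
        while True:
            chrom = chroms[rng.integers(0, len(chroms))]
            L = spec.chrom_lengths[chrom]
            pos = int(rng.integers(int(0.05 * L), int(0.95 * L)))
            if self._clear_position(chrom, pos):
                return chrom, pos

    def _clear_position(self, chrom: str, pos: int, buffer: int = 2_500) -> bool:
        """Away from anchored loci (1.1 Mb) and filter regions (2.5 kb)."""
        spec = self.spec
        for iv in spec.anchors.values():
            if iv.chrom == chrom and iv.distance_to(pos) <= 1_100_000:
                return False
        for iv in [*spec.blacklist, *spec.low_mappability]:
            if iv.chrom == chrom and iv.distance_to(pos) <= buffer:
                return False
        return True

    def _amp_near(self, rng, chrom: str, pos: int, distance: int) -> tuple[int, int, float]:
        """A focal amplification whose nearest boundary is exactly
        ``distance`` bp from ``pos``, on a random side."""
        length = int(rng.integers(100_000, 600_000))
        L = self.spec.chrom_lengths[chrom]
        if rng.random() < 0.5 and pos + distance + length < L:
            start = pos + distance
        else:
            start = max(0, pos - distance - length)
        return (start, start + length, self.config.focal_amp_log2)

    # ----------------------------------------------------------------- segments
    def _build_segments(self, rng, sample, gained: set, focal_plan) -> list[dict]:
        cfg, spec = self.config, self.spec
        rows = []
        for chrom, L in spec.chrom_lengths.items():
            base = cfg.hd_gain_log2 if chrom in gained else 0.0
            focals = sorted(focal_plan.get(chrom, []))
            cuts = {0, L}
            for s, e, _ in focals:
                cuts.add(int(s))
                cuts.add(int(min(e, L)))
            for _ in range(rng.poisson(2)):
                cuts.add(int(rng.integers(1, L)))
            edges = sorted(cuts)
            for lo, hi in zip(edges, edges[1:]):
                delta = sum(v for s, e, v in focals if s <= lo and hi <= e)
                value = base + delta + float(rng.normal(0.0, cfg.cna_noise_sd))
                rows.append(
                    {"sample": sample, "chrom": chrom, "start": lo, "end": hi,
                     "log2": round(value, 4)}
                )
        return rows

    # ---------------------------------------------------------------- artifacts
    def _make_artifact(self, rng, sample, name, reason) -> TranslocationCall:
        spec = self.spec
        if reason == "blacklist":
            iv = spec.blacklist[rng.integers(0, len(spec.blacklist))]
            chrom_a, pos_a = iv.chrom, int(rng.integers(iv.start, iv.end))
            chrom_b, pos_b = self._draw_random_position(rng)
        elif reason == "low_mappability":
            iv = spec.low_mappability[rng.integers(0, len(spec.low_mappability))]
            chrom_a, pos_a = iv.chrom, (iv.start + iv.end) // 2
            chrom_b, pos_b = self._draw_random_position(rng)
        else:  # homologous flanks
            chrom_a, pos_a = self._draw_random_position(rng)
            while True:
                chrom_b, pos_b = self._draw_random_position(rng)
                if chrom_b != chrom_a:
                    break
            # copy 160 bp from the A flank into the B flank with 12 planted
            # mismatches: every 100 bp window keeps >= 88% identity
            src = pos_a + int(rng.integers(-500, 340))
            dst = pos_b + int(rng.integers(-500, 340))
            mism = rng.choice(160, size=12, replace=False)
            self._homology_patches.append((chrom_a, src, chrom_b, dst, mism))
        total = max(1, int(rng.poisson(self.config.read_depth)))
        spanning = int(rng.binomial(total, 0.15))
        return TranslocationCall(
            sample=sample, chrom_a=chrom_a, pos_a=pos_a, chrom_b=chrom_b, pos_b=pos_b,
            strand_a="+", strand_b="-", spanning_reads=spanning, total_reads=total,
            name=name,
        )

    # --------------------------------------------------------------- expression
    def _draw_expression(self, rng, sample) -> dict:
        cfg = self.config
        from .expression import IGH_CONSTANT_ORDER

        isotype = _weighted_choice(rng, cfg.isotype_weights)
        row = {"sample": sample}
        for c in IGH_CONSTANT_ORDER:
            row[c] = round(float(rng.uniform(10, 800)), 2)
        if isotype == "none":
            # a clearly dominant constant region that still misses the floor
            top = IGH_CONSTANT_ORDER[rng.integers(0, len(IGH_CONSTANT_ORDER))]
            row[top] = round(float(rng.uniform(1_000, 4_800)), 2)
        else:
            row[isotype] = round(5_000 * float(np.exp(rng.uniform(0.05, 1.2))), 2)
        kappa = bool(rng.random() < cfg.kappa_frac)
        hi = round(float(rng.uniform(4_000, 20_000)), 2)
        lo = round(float(rng.uniform(50, 1_500)), 2)
        row["IGK"], row["IGL"] = (hi, lo) if kappa else (lo, hi)
        row["_isotype_truth"] = isotype
        row["_light_chain_truth"] = "kappa" if kappa else "lambda"
        return row

    # -------------------------------------------------------------------- peaks
    def _simulate_peaks(self, rng):
        cfg, spec = self.config, self.spec
        tss = []
        for _ in range(cfg.n_tss):
            chrom, pos = self._draw_random_position(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append(Interval(chrom, pos, pos + 1, name=f"tss{len(tss)}", strand=strand))
        self.tss = tss

        peaks = []
        for _ in range(cfg.n_background_peaks):
            chrom, pos = self._draw_random_position(rng)
            width = int(rng.integers(200, 800))
            peaks.append((chrom, pos, pos + width, float(rng.exponential(0.8) + 0.05)))
        # peaks parked on promoters: excluded before stitching
        promoter_tss = rng.choice(len(tss), size=cfg.n_promoter_peaks, replace=False)
        for t_idx in promoter_tss:
            t = tss[t_idx]
            pos = t.start if t.strand != "-" else t.end - 1
            start = max(0, pos - int(rng.integers(0, 2_000)))
            peaks.append((t.chrom, start, pos + 200, float(rng.exponential(0.8) + 0.05)))
        # planted super-enhancer clusters, spaced out deterministically
        supers = []
        hd = HD_CHROMS
        for j in range(cfg.n_super):
            chrom = hd[j % len(hd)]
            base = int(1_000_000 + (j // len(hd)) * 1_500_000 + rng.integers(0, 200_000))
            n_peaks = int(rng.integers(3, 6))
            pos = base
            cluster = []
            for _ in range(n_peaks):
                width = int(rng.integers(1_000, 3_000))
                cluster.append((chrom, pos, pos + width, float(rng.uniform(12, 40))))
                pos += width + int(rng.integers(2_000, 12_000))
            peaks.extend(cluster)
            supers.append(
                {"chrom": chrom, "start": cluster[0][1], "end": cluster[-1][2],
                 "n_peaks": n_peaks,
                 "signal": round(sum(p[3] for p in cluster), 4)}
            )
        self.peaks = pd.DataFrame(
            peaks, columns=["chrom", "start", "end", "signal"]
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
        self.peaks["signal"] = self.peaks["signal"].round(4)
        self.truth["super_enhancers"] = supers

    # ------------------------------------------------------------------- tracks
    def _build_mappability(self) -> MappabilityTrack:
        spec = self.spec
        steps = {}
        for chrom, L in spec.chrom_lengths.items():
            zones = sorted(
                (z.start, z.end) for z in spec.low_mappability if z.chrom == chrom
            )
            starts, ends, values = [], [], []
            cursor = 0
            for zs, ze in zones:
                if zs > cursor:
                    starts.append(cursor); ends.append(zs); values.append(1.0)
                starts.append(zs); ends.append(ze); values.append(0.05)
                cursor = ze
            if cursor < L:
                starts.append(cursor); ends.append(L); values.append(1.0)
            steps[chrom] = (
                np.array(starts), np.array(ends), np.array(values, dtype=float)
            )
        return MappabilityTrack(steps)

    # ------------------------------------------------------------------- genome
    @property
    def genome(self) -> GenomeAssembly:
        """Toy genome sequence (built on first access; deterministic)."""
        if self._genome is None:
            rng = np.random.default_rng(self._genome_seed)
            seqs = {}
            for chrom, L in self.spec.chrom_lengths.items():
                seqs[chrom] = _random_sequence(rng, L)
            for chrom_a, src, chrom_b, dst, mism in self._homology_patches:
                copy = seqs[chrom_a][src : src + 160].copy()
                for m in mism:
                    current = copy[m]
                    options = _BASES[_BASES != current]
                    copy[m] = options[rng.integers(0, 3)]
                seqs[chrom_b][dst : dst + 160] = copy
            self._genome = GenomeAssembly(
                {c: s.tobytes().decode("ascii") for c, s in seqs.items()}
            )
        return self._genome

    # -------------------------------------------------------------- annotations
    @property
    def annotations(self) -> AnnotationSet:
        spec = self.spec
        ann = AnnotationSet()
        ann.add_category("csr", spec.csr)
        ann.add_category("vd", [spec.vd])
        ann.add_category("loci", list(spec.anchors.values()))
        ann.add_category("table1", spec.table1)
        ann.add_category("tss", self.tss)
        ann.add_category("blacklist", spec.blacklist)
        return ann

    def anchor(self, name: str) -> Interval:
        return self.spec.anchors[name]

    # -------------------------------------------------------------------- write
    def write(self, outdir, with_genome: bool = True) -> dict[str, Path]:
        """Emit every input file plus truth.json; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        spec = self.spec
        paths = {}

        def _p(key, name):
            paths[key] = out / name
            return paths[key]

        mio.write_breakpoint_pairs(self.calls, _p("calls", "calls.bedpe"))
        mio.write_cna_segments(self.segments, _p("segments", "cna_segments.seg"))
        mio.write_intervals(spec.csr, _p("csr", "csr.bed"))
        mio.write_intervals([spec.vd], _p("vd", "vd.bed"))
        mio.write_intervals(list(spec.anchors.values()), _p("loci", "loci.bed"))
        mio.write_intervals(spec.table1, _p("table1", "table1_regions.bed"))
        mio.write_intervals(self.tss, _p("tss", "tss.bed"))
        mio.write_intervals(spec.blacklist, _p("blacklist", "blacklist.bed"))
        mio.write_mappability(self.mappability, _p("mappability", "mappability.bedgraph"))
        mio.write_table(self.survival, _p("survival", "survival.tsv"))
        expr = self.expression.drop(columns=["_isotype_truth", "_light_chain_truth"])
        mio.write_table(expr.reset_index(), _p("expression", "expression.tsv"))
        mio.write_peaks(self.peaks, _p("peaks", "peaks.bed"))
        if with_genome:
            mio.write_genome(self.genome, _p("genome", "genome.fa"))
        with open(_p("truth", "truth.json"), "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1)
        return paths


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _config_digest(cfg: CohortConfig) -> str:
    payload = json.dumps(_jsonable(asdict(cfg)), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``seed``."""
    return SyntheticCohort(config or CohortConfig(), seed)


# -------------------------------------------------------------------- fixtures
def simulate_hotspot_calls(
    n_samples: int,
    frequency: float,
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
    partner_chrom: str = "chrX",
    partner_pos: int = 100_000,
) -> list[TranslocationCall]:
    """Calls for a planted hotspot: a ``frequency`` fraction of samples get
    one breakpoint uniform in [start, end); useful for recovery tests."""
    rng = np.random.default_rng(seed)
    n_hit = int(round(frequency * n_samples))
    hit = set(rng.choice(n_samples, size=n_hit, replace=False))
    calls = []
    for i in sorted(hit):
        calls.append(
            TranslocationCall(
                sample=f"H{i:04d}",
                chrom_a=chrom, pos_a=int(rng.integers(start, end)),
                chrom_b=partner_chrom, pos_b=partner_pos,
                spanning_reads=10, total_reads=40, name=f"H{i:04d}_h0",
            )
        )
    return calls


def plant_identity_pair(
    rng: np.random.Generator,
    n_matches: int,
    flank_bp: int = 1000,
    window_bp: int = 100,
) -> tuple[str, str]:
    """Two random flanks whose maximum 100 bp window identity is exactly
    ``n_matches``/``window_bp``.

    A window copied from A is written into B with exactly
    ``window_bp - n_matches`` interior mismatches; 5 guard mismatches on
    each side of the copy stop shifted windows from scoring higher.
    """
    if not window_bp // 2 <= n_matches <= window_bp:
        raise ValidationError("planted identity must be in [window/2, window]")
    a = _random_sequence(rng, flank_bp)
    b = _random_sequence(rng, flank_bp)
    guard = 5
    src = int(rng.integers(guard, flank_bp - window_bp - guard))
    dst = int(rng.integers(guard, flank_bp - window_bp - guard))
    copy = a[src : src + window_bp].copy()
    n_mismatch = window_bp - n_matches
    if n_mismatch:
        # interior, evenly spread so small shifts keep all of them in-window
        sites = np.linspace(10, window_bp - 11, n_mismatch).astype(int)
        for m in np.unique(sites):
            copy[m] = _other_base(rng, copy[m])
    b[dst : dst + window_bp] = copy
    for g in range(1, guard + 1):
        if dst - g >= 0 and src - g >= 0:
            b[dst - g] = _other_base(rng, a[src - g])
        if dst + window_bp + g - 1 < flank_bp and src + window_bp + g - 1 < flank_bp:
            b[dst + window_bp + g - 1] = _other_base(rng, a[src + window_bp + g - 1])
    return a.tobytes().decode(), b.tobytes().decode()


def _other_base(rng, base: np.uint8) -> np.uint8:
    options = _BASES[_BASES != base]
    return options[rng.integers(0, 3)]


def generate_homology_fixtures(
    seed: int = 0,
    planted: tuple[int, ...] = (60, 70, 79, 80, 85, 95, 100),
    n_random: int = 20,
    flank_bp: int = 1000,
) -> list[dict]:
    """Flank pairs with known maximum window identity: planted pairs have an
    exact identity; random pairs have none planted (background only)."""
    rng = np.random.default_rng(seed)
    fixtures = []
    for m in planted:
        a, b = plant_identity_pair(rng, m, flank_bp)
        fixtures.append({"seq_a": a, "seq_b": b, "planted_matches": m})
    for _ in range(n_random):
        fixtures.append(
            {
                "seq_a": _random_sequence(rng, flank_bp).tobytes().decode(),
                "seq_b": _random_sequence(rng, flank_bp).tobytes().decode(),
                "planted_matches": None,
            }
        )
    return fixtures


# ------------------------------------------------------- survival-only cohorts
def simulate_survival_cohort(
    n: int,
    log_hr: float = 0.0,
    p_group: float = 0.5,
    baseline_hazard: float = 0.25,
    censoring_frac: float = 0.30,
    seed: int = 0,
) -> pd.DataFrame:
    """A two-group exponential survival cohort with a planted log hazard
    ratio and independent exponential censoring at the requested fraction."""
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < p_group).astype(int)
    h = baseline_hazard * np.exp(log_hr * group)
    t_event = rng.exponential(1.0 / h)
    c = censoring_frac
    t_censor = rng.exponential((1 - c) / (c * h))
    return pd.DataFrame(
        {
            "time": np.minimum(t_event, t_censor),
            "event": (t_event <= t_censor).astype(int),
            "group": group,
        }
    )
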