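# mmsv

Downstream structural-variant analysis for multiple myeloma whole-genome
sequencing cohorts.

Multiple myeloma genomes bifurcate into two founding lesions: clonal
immunoglobulin heavy-chain (IgH) translocations arising from class-switch
recombination errors, and hyperdiploidy (whole-chromosome gains of the
odd-numbered chromosomes). On top of these sit sub-clonal secondary events
— MYC translocations flanked by focal amplifications, and immunoglobulin
light-chain (IgL) translocations that mark poor prognosis and resistance
to IMiD therapy. `mmsv` implements the computations needed to work with
such cohorts downstream of an SV caller:

* **Translocation QC** — flank-homology filter (≥ 80% ungapped identity in
  any 100 bp window within 1 kb of the junction), mappability filter
  (< 20% mean over 1 kb flanks), blacklist filter; VAF-based clonality
  (VAF = spanning reads / total breakpoint-spanning reads; ≈ 0.5 for a
  clonal heterozygous event); CSR / VD / extragenic breakpoint
  classification with odds-ratio location biases.
* **Hotspot discovery** — 1 Mb windows advanced in 0.5 Mb steps; windows
  with ≥ 1% of samples translocated are stitched into recurrent regions;
  partner-pair frequencies within 1 Mb of two anchor loci.
* **Copy-number cytogenetics** — length-weighted binning and region calls
  (gain ≥ +0.2, loss ≤ −0.2 log2); hyperdiploidy as concordant gains of
  both control regions on ≥ 4 eligible chromosomes; del(1p), amp(1q),
  del(13), del(17p); distance from breakpoints to copy-number state-change
  boundaries (≤ 10 kb = proximal); Fisher exact co-occurrence with BH FDR.
* **Survival** — Kaplan–Meier and Cox proportional-hazards (lifelines
  underneath), count-scaled hazard ratios, a label-permutation bootstrap
  p-value for hazard ratios (B = 1000, +1-corrected, two-sided on
  |log HR|), and matched downsampling for unequal group sizes.
* **Super-enhancers** — ROSE-style stitching of occupancy peaks within
  15 kb (promoter peaks excluded: 2.5 kb strand-aware upstream of each
  TSS), ranking by reads-per-million, and the slope-1 tangent inflection
  cutoff.
* **Expression typing** — heavy-chain isotype (argmax constant region,
  ≥ 5000 FPKM) and light-chain (higher cumulative IgK vs IgL) calls.
* **Synthetic cohort generator** — a seeded, fully deterministic toy
  cohort (genome, annotations, BEDPE calls, SEG segments, survival and
  expression tables, mappability, peaks) with a truth file, emulating the
  statistical structure of a newly diagnosed cohort: clonal CSR-anchored
  IgH events, sub-clonal MYC events abutting focal amplifications,
  hyperdiploid profiles, a planted t(IgL)×IMiD survival interaction, and
  peak curves with a planted super-enhancer elbow.

Real patient data of this kind are controlled-access; the generator makes
every stage testable end-to-end without any download. See
`docs/methods.md` for models, defaults, and design decisions.

## Worked example

```python
from mmsv.simulate import CohortConfig, generate_cohort
from mmsv import hotspots, survival

cohort = generate_cohort(CohortConfig(n_samples=300), seed=42)
N = cohort.config.n_samples

grid = hotspots.window_sample_frequency(cohort.calls, cohort.spec.chrom_lengths, N)
for r in sorted(hotspots.stitch_hotspots(grid, cohort.calls, N, min_freq=0.05),
                key=lambda r: -r.frequency):
    print(f"{r.chrom}:{r.start}-{r.end}  freq={r.frequency:.3f}  median VAF={r.median_vaf:.2f}")

est = survival.cox_fit(cohort.survival, ["t_igl"])[0]
boot = survival.bootstrap_hr_pvalue(cohort.survival, "t_igl", B=1000, seed=42)
print(f"t(IgL) HR {est.hr:.2f} (95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f}), "
      f"Wald p {est.p:.2g}, bootstrap p {boot.p:.3f}")
```

prints

```
chr1:3500000-5500000  freq=0.447  median VAF=0.48
chr2:2500000-4500000  freq=0.207  median VAF=0.26
chr5:1000000-3000000  freq=0.183  median VAF=0.50
chr6:1000000-3000000  freq=0.140  median VAF=0.48
chr3:2500000-4000000  freq=0.083  median VAF=0.23
t(IgL) HR 3.31 (95% CI 2.07-5.28), Wald p 5.5e-07, bootstrap p 0.001
```

The hotspot table recovers the planted architecture: the IgH region
(chr1) is the most frequently translocated and clonal (median VAF ≈ 0.48),
the MYC region (chr2) is common but sub-clonal (VAF ≈ 0.26), the partner
loci CCND1/WHSC1 (chr5/chr6) are clonal, and the IgL region (chr3) sits
near 10% of samples at sub-clonal VAF. The Cox fit recovers the planted
t(IgL) hazard (the generator plants HR 2.0 plus an IMiD interaction that
inflates the marginal estimate), and the permutation bootstrap confirms
the Wald test.

## Command line

The `mmsv` console script exposes each stage
(`simulate`, `qc`, `classify-breakpoints`, `hotspots`, `cna`, `cooccur`,
`survival`, `superenhancer`, `expression`, `report`) and `run-all`, which
chains them on a simulated cohort and writes per-stage TSVs plus
`summary.json` with a provenance block (package version, seed, config
digest):

```bash
mmsv run-all --seed 1 --outdir runs/demo --bootstrap 200
mmsv report --rundir runs/demo
```

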