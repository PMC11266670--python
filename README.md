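# cadpipe

Chromatin accessibility dynamics (CAD) analysis for two-condition
reprogramming time courses.

During somatic-cell reprogramming the open-chromatin landscape moves from
the fibroblast (MEF) pattern toward the pluripotent (ESC) pattern. When two
reprogramming conditions are profiled over the same time course — e.g. a
wild-type factor versus an engineered variant that recruits the BAF
chromatin remodeller — the interesting loci are the ones that open or close
in one condition but not the other. `cadpipe` implements that comparison as
a reusable, fully tested pipeline for computational biologists working with
ATAC-seq/CUT&Tag peak sets, signal tables, expression matrices and pull-down
proteomics at desk scale.

## What it computes

**Temporal CO/OC grouping.** Peak calls per timepoint are binarized onto a
merged locus universe flanked by MEF and ESC reference states. Each locus is
labelled by the timepoint at which it transitions closed→open (CO1..CO9) or
open→closed (OC1..OC9): with eight course timepoints, CO9 means "closed
through day 12 but open in ESC" and OC1 "open in MEF, closed from day 0".
The label is the nearest ideal step pattern; loci more than
`flicker_tolerance` timepoints away from every template are `complex`.

**Failed-to-open / failed-to-close.** Comparing two condition trajectories
over the reprogramming groups (CO1–CO8, OC2–OC9) yields the loci dynamic in
condition B whose condition-A trajectory never moved by the final timepoint.

**Co-occupancy codes.** Binding regions get a 4-bit code over
(NANOG_WT, NANOG_BiD, BRG1_WT, BRG1_BiD) peak presence — the 0101/0100/
1101/1100 classes — with per-class signal summaries and annotation
enrichment.

**Association and enrichment statistics.**

- Region→gene association by the GREAT-like distance rule: upstream 5 kb,
  downstream 2 kb, distal 100 kb of the TSS, plus promoter (TSS ± 2 kb)
  overlap.
- Permutation overlap enrichment: z = (obs − μ₀)/σ₀ against a
  chromosome- and length-preserving uniform relocation null.
- Known-motif enrichment in summit ± 25 bp windows with a hypergeometric
  right tail; motifs reported at fold ≥ 3 and p < 1e-5.
- Composite regulator ranking: genome bins are cross-tabulated by (overlaps
  query, overlaps factor peaks) and factors ranked by
  score = (−log₁₀ p)·log₂(odds ratio) from a right-tailed Fisher test.

**Omics integration.** A pseudocounted log2 fold-change DE score (strict
> 0.5), k-means clustering of z-scored FPKM time courses, the pull-down
interactor filter chain (detected in both replicates, log2 enrichment
strictly > 1.2, Welch-t p < 0.05, statuses WT-specific / BiD-specific /
shared), and intersection of an expression cluster with the genes of
condition-sensitive CO regions.

**Synthetic data with planted truth.** `cadpipe.synthetic_data` generates a
miniature two-condition dataset — transition days, failure sets,
co-occupancy codes, one enriched compendium factor, cluster memberships,
true interactors — so every stage is verifiable without downloads. In the
noise-free setting each stage recovers its planted labels exactly.

## Worked example

```python
from cadpipe import synthetic_data as synth, cad_dynamics as cad, \
    association_enrichment as enr

assembly = synth.make_genome(n_chroms=2, chrom_length=2_000_000, seed=0)
sim = synth.make_accessibility_timecourse(assembly, n_loci_per_group=50,
                                          flicker_rate=0.02, seed=1)
ga = {}
for cond in ("BiD", "WT"):
    pm = cad.build_presence(sim.peaksets[cond], sim.mef_peaks, sim.esc_peaks,
                            universe=sim.loci)
    ga[cond] = cad.assign_groups(pm, flicker_tolerance=1)
    total = cad.summarize_groups(ga[cond]).co_reprogramming_total
    print(f"{cond}: {total} loci open during reprogramming (CO1-CO8)")

comp = cad.compare_trajectories(ga["BiD"], ga["WT"])
print(f"failed to open in WT: {len(comp.failed_to_open)} loci "
      f"({comp.early_open_fraction:.0%} of early CO groups)")

z = enr.permutation_z(comp.failed_to_open, sim.esc_peaks, assembly,
                      n_permutations=1000, seed=0)
print(f"enrichment of failed-to-open loci in ESC-open regions: z = {z.z:.1f}")
```

Output:

```
BiD: 402 loci open during reprogramming (CO1-CO8)
WT: 212 loci open during reprogramming (CO1-CO8)
failed to open in WT: 191 loci (48% of early CO groups)
enrichment of failed-to-open loci in ESC-open regions: z = 35.9
```

The engineered condition (BiD) opens about twice as many loci during the
course as the wild-type-like condition; the loci that failed to open in WT
are strongly enriched in regions that are open in the destination ESC
state — the generator plants exactly this structure, and the pipeline
recovers it.

## Command line

```bash
cadpipe all --seed 1 --outdir out/        # simulate + every analysis stage
cadpipe dynamics --config cfg.yaml --outdir out/
```

Stages run in dependency order; every output is a BED/TSV text file, and
`manifest.yaml` records the resolved config, seed and a sha256 per output.
Reruns with the same config are byte-identical.

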