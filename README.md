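# chromkit

Integrative regulatory-genomics analysis of how a promoter-bound nuclear
factor organizes transcription: histone-domain breadth stratification,
super-enhancer (SE) calling with occupancy marking, G-quadruplex (G4)
propensity scoring, and promoter–enhancer loop/hub analysis with
condition-response clustering — the analysis layer of a study of nuclear
miR-9 at TGFB1-responsive genes, built for epigenomics analysts who want the
published filtering rules and statistics as reusable, tested code.

Because the original deposited sequencing data are not required, the package
ships a seeded synthetic-data generator that emulates the statistical
structure of every input (peak-width mixtures, clustered enhancer
constituents, SE-biased miRNA marking, planted G4 tracts, condition-dependent
interaction frequencies, planted differential expression) with ground-truth
tables, so every stage is exercised and validated end to end.

## The methods at the core

* **Broad H3K4me3 domains.** Peak widths are stratified at their own
  quartiles: width ≥ Q3 → broad, Q2 ≤ width < Q3 → medium, width < Q2 →
  narrow. Peaks are annotated promoter (TSS ± 2 kb) / gene body / intergenic,
  condition shifts are tested with a two-tailed Fisher exact test, and
  category distributions are compared as log2((obs+1)/(ref+1)).
* **ROSE-style SE calling.** H3K27ac constituents within 12.5 kb are
  stitched; stitched enhancers are ranked by background-subtracted signal;
  on the min–max-scaled rank curve the cutoff is the first ascending point
  whose discrete slope exceeds 1 (the "hockey stick" tangent rule);
  enhancers above it are SEs, the rest typical enhancers (TYE). An enhancer
  is miRNA-marked when a miRNA occupancy peak overlaps one of its
  constituents; SE-vs-TYE marking enrichment is a Fisher exact test.
* **G4Hunter-style scoring.** Per-base scores +min(run,4) for G runs and
  −min(run,4) for C runs, averaged in 25-nt sliding windows; maximal runs of
  windows ≥ 1.2 become G4 candidate regions, usable to filter peak sets.
  An IUPAC scanner locates degenerate motifs such as the expanded nuclear
  shuttling motif 5'-AKYACCWUUUGRUWA-3'.
* **Loops and hubs.** Interaction pairs are binned (25 kb); a hub is an
  anchor bin with its summed contact frequency, filtered at ≥ 10 and
  normalized to the retained-set mean. Loops connect a TSS ± 2 kb window to
  an H3K4me3 peak anchor, pass a distance-matched background-quantile
  filter (echoing p ≤ 0.01), and their per-condition log2 ratios to control
  are grouped by seeded k-means (k = 4).
* **Expression.** RPKM quantification; genes with log2FC ≤ −0.58 / ≥ 0.58
  are classed down / up.

## Worked example

```sh
chromkit run-all --out demo_run --seed 1
```

generates synthetic inputs under `demo_run/simulated/` and runs every stage.
`demo_run/report.json` then contains (excerpt):

```json
"se_call": {
  "n_enhancers": 460, "n_se": 60, "n_tye": 400,
  "pct_se_mirna_marked": 26.67, "pct_tye_mirna_marked": 4.25,
  "cutoff_signal": 3086.09,
  "marking_fisher_p": 2.18e-07,
  "se_precision": 1.0, "se_recall": 1.0
},
"breadth": {"q2_bp": 1886.0, "q3_bp": 2701.25, "breadth_class_accuracy": 1.0},
"g4": {"n_g4_regions": 1917, "g4_tract_recovery": 1.0},
"loops": {"n_loops": 145, "cluster_agreement": 1.0}
```

Reading: of 460 stitched enhancers, the 60 planted SEs are recovered exactly
(precision/recall 1.0); 26.7% of SEs but only 4.3% of TYEs carry a miRNA
occupancy peak (Fisher p ≈ 2e-7), mirroring the planted 25% vs 4% marking
probabilities; the empirical width quartiles (Q3 ≈ 2.7 kb) reproduce the
planted breadth mixture with 100% class accuracy; all planted G4 tracts are
rediscovered by window scoring; and the four planted loop-response
archetypes are recovered perfectly by k-means on the log2-ratio profiles.

Each stage is also available separately (`chromkit simulate`, `breadth`,
`se-call`, `g4`, `loops`, `stats`) and as plain library calls
(`chromkit.enhancer_rose.rank_and_cutoff`, ...).

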