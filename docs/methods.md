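# Methods

## Coordinate model

All coordinates are 0-based half-open (BED convention); 1-based inputs would
be converted at the reader boundary. Overlap means ≥ 1 shared base, so
bookended intervals do not overlap but do merge at gap 0. Strand is carried
but ignored by overlap operations, matching the strand-agnostic
intersections of the upstream peak toolchain. Sorting ties are broken by
(start, end, name) so every output is deterministic.

## Histone-domain breadth

Breadth classes are defined from the peak set's own width distribution:
Q1/Q2/Q3 are the 25/50/75-percentiles under linear interpolation (the common
default; the quantile method is configurable). The partition is exhaustive at
Q2/Q3 — broad ≥ Q3, medium [Q2, Q3), narrow < Q2. Two descriptions of
"narrow" circulate for this kind of analysis (bottom quartile vs everything
below the median); we adopt the three-way exhaustive partition so that every
peak is classified and class counts sum to n.

Region annotation uses promoter = TSS ± 2 kb (clipped at chromosome bounds),
then gene body = anywhere in the exon–intron span, then intergenic, with
promoter taking precedence. Gene-body peaks get an exon/intron detail label;
finer UTR/TTS sub-labels are not produced because the gene model carries no
UTR structure. Distribution shifts between conditions are reported as
log2((obs_c + 1)/(ref_c + 1)) per category — the pseudocount of 1 keeps
ratios finite for empty categories — and breadth shifts are tested with the
two-tailed Fisher exact test on (focus class vs rest) × (condition A vs B).

## Super-enhancer calling

Constituent peaks within 12,500 bp are stitched (the standard
rank-ordering default; configurable). TSS exclusion is off by default, again
matching the default of the published procedure, and can be enabled by
passing promoter windows. Enhancer signal is the summed signal-track
coverage over the stitched region, minus the matched background coverage,
floored at 0.

The SE cutoff operates on the min–max-scaled (rank, signal) curve: scanning
ascending, the cutoff is the first index whose discrete slope over adjacent
points exceeds 1; enhancers with net signal strictly above the signal at
that index are SEs. This makes the SE/TYE partition exactly reproducible and
invariant to affine rescaling of the signal vector. With a flat curve no
point has slope > 1 and no SE is called; an all-zero signal vector is
rejected as degenerate.

Size strata use half-open classes with inclusive lower bounds: SE narrow
< 2.3 kb, medium [2.3, 3.2) kb, broad ≥ 3.2 kb; TYE narrow < 0.6 kb, medium
[0.6, 0.9) kb, broad ≥ 0.9 kb. The published figure legend prints strict
inequalities that leave the exact boundary widths unassigned; the half-open
convention makes the partition exhaustive while agreeing everywhere else.

Marking: an enhancer is miRNA-marked when ≥ 1 miRNA occupancy peak shares
≥ 1 base with ≥ 1 constituent peak. The marking rule deliberately tests
constituents rather than the stitched span (a peak landing in a stitched gap
does not mark); `on="span"` switches to the whole region.

## G4 propensity

Scores follow the run-length scheme: each base of a maximal G run of length
L scores +min(L, 4), each base of a C run −min(L, 4), everything else 0; N
scores 0 and U ≡ T throughout. Window scores are sliding arithmetic means
(default 25 nt); sequences shorter than the window get a single whole-
sequence mean. Candidate regions are maximal runs of windows ≥ threshold
(default 1.2, the published genome-scan default), spanning first window
start to last window end, with the mean recomputed over the merged span. No
sub-window trimming/refinement is performed — regions are window-run unions,
the simplest reproducible definition.

In IUPAC scanning, degenerate codes in the *pattern* expand over {A,C,G,T}
only, so an N in the *sequence* never matches (including against pattern N).
Overlapping matches are reported; minus-strand hits are mapped back to
plus-strand coordinates of their leftmost base.

## Hubs, loops, response clustering

Interaction anchors snap to fixed-resolution bins (default 25 kb) and
coincident pairs aggregate under unordered-pair identity. A hub is a bin
with the summed frequency of every pair touching it (self-pairs counted
once); hubs with total ≥ 10 are retained and normalized to the retained-set
mean, so normalized frequencies average to exactly 1. Conditions are
equalized by down-sampling interaction events without replacement
(multivariate hypergeometric), which conserves the target total exactly and
is reproducible per seed.

Loop calls connect a TSS ± 2 kb window to an H3K4me3-peak anchor; identical
anchor bins and pairs whose two anchors share one TSS window are excluded as
self-loops. Significance is a transparent filter standing in for a
likelihood model: non-candidate pairs form a distance-matched background
(log2-spaced distance strata), and a candidate is kept when its best
per-condition frequency exceeds the background's 0.99 quantile in its
stratum (echoing p ≤ 0.01; the quantile is configurable and the filter can
be disabled). The background is restricted to non-candidates because real
loops would otherwise contaminate their own null.

Response profiles are log2((f_c + 1)/(f_Ctrl + 1)) per non-control
condition; k-means (k = 4, seeded, 10 restarts, scikit-learn) groups the raw
profiles. Per-locus standardization is available but off by default — with
ratio profiles the magnitude of the response is part of the signal. With
degenerate (identical) profiles the clustering still returns k centroids,
with empty clusters handled by the library's deterministic relocation.

## Shared statistics

* Fisher exact (two-tailed): probability-mass convention — the sum of
  hypergeometric probabilities of all same-margin tables whose probability
  is ≤ that observed (relative tolerance 1e-7). This is the common
  convention (R, scipy) but differs from p-doubling, hence documented.
* RPKM: counts / (exon kb × mapped reads / 1e6); total mapped reads as the
  library size.
* Differential classes: log2FC ≤ −0.58 down, ≥ +0.58 up, boundaries
  inclusive as printed.
* Percentages: rounded half-up to one decimal, matching the reporting style.
* Z-score matrices: row-wise with sample sd (n − 1); constant rows are an
  error naming the offending factor.
* Rank tests: classic equal-variance t-test (degenerate variance is an
  error) and Wilcoxon rank-sum, exact for ≤ 25 combined tie-free
  observations.
* No multiple-testing correction is applied by default (none of the
  reproduced figures applies one); Benjamini–Hochberg is available as a
  hook.

## Synthetic data: what it emulates, and what it does not

The generator plants, per seed, deterministically:

* **Breadth mixture** — 2,000 peaks, widths from three well-separated normal
  modes (narrow 1.2 ± 0.15 kb 50%, medium 2.35 ± 0.09 kb 25%, broad
  3.6 ± 0.28 kb 25%) with exact per-class counts, so the empirical Q2/Q3
  land in the gaps between modes (≈ 1.9/2.7 kb, close to the reported
  domain bounds of 2.0/2.7 kb) and class recovery is essentially exact.
* **Enhancers** — 60 SE units (Poisson-5 constituents, 0.9 ± 0.12 kb wide,
  gaps 0.2–2.2 kb, ~15 signal/bp) and 400 TYE singletons (0.75 ± 0.15 kb,
  ~3 signal/bp), units ≥ 13 kb apart so stitching at 12.5 kb reconstructs
  exactly the planted units; a flat 0.5/bp background track exercises
  control subtraction.
* **Marking** — SE marked with probability 0.25, TYE 0.04 (the reported
  25.5% vs 4%); promoter occupancy peaks are placed only at promoters clear
  of enhancer constituents so they cannot perturb the planted marking rates.
* **G4 tracts** — (GGG N)×4 tracts with A/T loops of 1–3 nt at 10/Mb on a
  2 × 5 Mb genome at GC 0.42. Short loops are the stable-G4 regime and keep
  every planted tract detectable at window 25 / threshold 1.2: with loops
  summing beyond ~13 nt a 25-nt window cannot average 1.2 over a tract
  (peak window mean ≈ 1.08), so long-loop tracts are intrinsically invisible
  to the default scan — the configurable `g4_loop_min/max` expose that
  regime, and this detectability limit is a property of the scoring scheme,
  not of the generator.
* **Loops** — 4 × 50 promoter–SE pairs with response archetypes (log2
  multipliers (2,2), (2,−2), (0,0), (−2,−2) vs control, σ = 0.1 in log
  space) on negative-binomial baselines (mean 30), plus 2,000
  distance-decay/uniform background pairs; expression — negative-binomial
  counts (dispersion 100) with 30% of genes planted at ±1.2 log2FC, split
  73.5% down / 26.5% up, mirroring the published proportions.

Passing recovery tests on these data shows the algorithms implement their
definitions and recover planted structure under realistic noise; it does
*not* show performance on real chromatin data, where peak-width modes
overlap, enhancer spacing is irregular, signal backgrounds are structured,
mappability artifacts exist, and contact matrices carry systematic biases
the generator does not model (no read-level simulation, no blacklist
regions, no matrix-balancing biases).

### Type-I calibration of the marking test

The calibration check plants *equal* marking probabilities and asks the
Fisher p-value to be approximately uniform across 200 generator seeds. An
exact conditional test is discrete and conservative: at small expected
marked counts (equal rates ≤ 0.1 with 200 SE / 2,000 TYE) its null
p-distribution visibly departs from uniform no matter how the test is
implemented. The calibration therefore plants equal marking at the SE rate
(0.25), where expected marked counts (~50 and ~500) are large enough for
near-uniformity; the Kolmogorov–Smirnov check then passes comfortably. This
is a simulation-design choice about where a uniformity approximation is
meaningful, not a property of the data generator.

## Numerical and degenerate-input choices

* Quantiles: linear interpolation; percentages: decimal half-up rounding.
* Down-sampling uses numpy's multivariate hypergeometric — exact totals,
  integer state, platform-independent per seed.
* Hub normalization divides by the float mean; the mean-of-normalized
  invariant holds to < 1e-12.
* Empty inputs raise early with specific messages (empty peak set for
  stitching, empty hub set after filtering, all-zero ranking signal, < 4
  widths for quantiles, fewer loci than k).
* All generator randomness flows from one `SeedSequence`; emitted files are
  byte-identical across runs and platforms.

## Problem sizes

Default synthetic conditions (2 × 5 Mb genome, 2,000 + 2,660 peaks, ~2,600
interaction pairs per condition, 300 genes) run the full pipeline in a few
seconds on one CPU; the calibration study (200 generator seeds at 200 SE /
2,000 TYE) adds ~10 s. These sizes give stable quantiles and enrichment
counts while staying desk-scale; genome-scale numbers from the original
deposited data (tens of thousands of hubs, thousands of SEs) are not
reproducible at this scale and are not targeted.

## Known limitations

* The hub definition (fixed-resolution bin with summed frequency) is a
  transparent reconstruction; the upstream tool's hub counts depend on its
  internals and real data, and are not comparable 1:1.
* The loop significance filter is an empirical quantile, not a genomic
  background likelihood model.
* G4 calling is propensity-based sequence scoring; it does not model
  folding thermodynamics or antibody-based signal.
* Breadth classes depend on the input peak set's own width distribution;
  comparing conditions assumes peak calling was performed consistently.
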