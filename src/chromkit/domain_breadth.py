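"""Quantile-based breadth classification of histone-mark domains.

Broad domains of H3K4me3 (peaks in the top width quartile) mark highly
transcribed, cell-identity genes; this module stratifies a peak set into
broad / medium / narrow classes from its own width distribution, annotates
peaks to promoter / gene-body / intergenic space, and provides the log2
distribution ratios and Fisher breadth-shift test used to compare conditions.

The three-way partition is exhaustive at the Q2/Q3 width quantiles:
width >= Q3 -> broad, Q2 <= width < Q3 -> medium, width < Q2 -> narrow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import GeneModel, GenomicInterval, IntervalSet, intersect
from .stats_report import ContingencyTable, fisher_exact_2x2

BREADTH_CLASSES = ("broad", "medium", "narrow")
COARSE_REGIONS = ("promoter", "gene_body", "intergenic")


@dataclass(frozen=True)
class BreadthThresholds:
    """Peak-width quantiles (bp) defining the breadth classes."""

    q1: float
    q2: float
    q3: float
    source_n: int

    def __post_init__(self) -> None:
        if not (self.q1 <= self.q2 <= self.q3):
            raise ValueError("require q1 <= q2 <= q3")
        if self.source_n < 4:
            raise ValueError("thresholds require >= 4 source peaks")


@dataclass
class BreadthClassification:
    """Per-peak breadth class plus the thresholds that produced it."""

    classes: np.ndarray  # of {"broad","medium","narrow"}
    thresholds: BreadthThresholds

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.classes == c)) for c in BREADTH_CLASSES}


@dataclass
class RegionAnnotation:
    """Per-peak coarse genomic-region label, with exon/intron detail when
    exon structure is available."""

    labels: np.ndarray  # of {"promoter","gene_body","intergenic"}
    detail: np.ndarray | None = None  # of {"exon","intron"} for gene_body peaks

    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in COARSE_REGIONS}


def compute_breadth_thresholds(widths: Sequence[float], method: str = "linear") -> BreadthThresholds:
    """25/50/75-percentiles of peak widths (linear interpolation by default)."""
    w = np.asarray(widths, dtype=float)
    if len(w) < 4:
        raise ValueError("too few peaks: need >= 4 widths for breadth quantiles")
    if np.any(w <= 0):
        raise ValueError("peak widths must be > 0")
    q1, q2, q3 = np.percentile(w, [25, 50, 75], method=method)
    return BreadthThresholds(q1=float(q1), q2=float(q2), q3=float(q3), source_n=len(w))


def classify_breadth(peaks: IntervalSet, thresholds: BreadthThresholds) -> BreadthClassification:
    """Classify each peak: width >= Q3 broad, Q2 <= width < Q3 medium, else narrow."""
    w = peaks.widths().astype(float)
    classes = np.full(len(w), "narrow", dtype=object)
    classes[w >= thresholds.q2] = "medium"
    classes[w >= thresholds.q3] = "broad"
    return BreadthClassification(classes=classes, thresholds=thresholds)


def annotate_region(
    peaks: IntervalSet,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2000,
) -> RegionAnnotation:
    """Annotate peaks as promoter / gene_body / intergenic.

    A peak overlapping any TSS +/- ``promoter_halfwidth`` window is a promoter
    peak; otherwise a peak overlapping a gene span (exons and introns) is
    gene_body; everything else intergenic. Precedence promoter > gene_body.
    Gene-body peaks get an exon/intron detail label (exon if they touch any
    exon).
    """
    chrom_len = peaks.genome or {}
    promoters = IntervalSet(
        [g.promoter(promoter_halfwidth, chrom_len.get(g.chrom)) for g in genes]
    )
    spans = IntervalSet([g.span for g in genes])
    exons = IntervalSet([e for g in genes for e in g.exons])
    in_prom = intersect(peaks, promoters, mode="count") > 0
    in_span = intersect(peaks, spans, mode="count") > 0
    in_exon = intersect(peaks, exons, mode="count") > 0
    labels = np.full(len(peaks), "intergenic", dtype=object)
    labels[in_span] = "gene_body"
    labels[in_prom] = "promoter"
    detail = np.full(len(peaks), "", dtype=object)
    body = labels == "gene_body"
    detail[body & in_exon] = "exon"
    detail[body & ~in_exon] = "intron"
    return RegionAnnotation(labels=labels, detail=detail)


def distribution_log2_ratio(
    counts_obs: Mapping[str, int],
    counts_ref: Mapping[str, int],
    pseudocount: float = 1.0,
) -> dict[str, float]:
    """Per-category log2((obs + pc) / (ref + pc)) distribution ratios.

    The pseudocount (default 1) keeps ratios finite for empty categories.
    """
    if set(counts_obs) != set(counts_ref):
        raise ValueError("observed and reference category keys differ")
    return {
        c: float(np.log2((counts_obs[c] + pseudocount) / (counts_ref[c] + pseudocount)))
        for c in counts_obs
    }


def breadth_shift_test(
    class_a: BreadthClassification,
    class_b: BreadthClassification,
    focus: str = "broad",
) -> float:
    """Two-tailed Fisher p for a shift of the ``focus`` class between A and B.

    Builds the 2x2 table (focus vs rest) x (A vs B).
    """
    if focus not in BREADTH_CLASSES:
        raise ValueError(f"unknown breadth class {focus!r}")
    if len(class_a.classes) == 0 or len(class_b.classes) == 0:
        raise ValueError("breadth classifications must be non-empty")
    a_focus = int(np.sum(class_a.classes == focus))
    b_focus = int(np.sum(class_b.classes == focus))
    table = ContingencyTable(
        a_focus, len(class_a.classes) - a_focus,
        b_focus, len(class_b.classes) - b_focus,
    )
    return fisher_exact_2x2(table)


def classification_table(peaks: IntervalSet, classification: BreadthClassification,
                         annotation: RegionAnnotation | None = None) -> pd.DataFrame:
    """Per-peak table of coordinates, width, breadth class and region label."""
    rows = {
        "chrom": [iv.chrom for iv in peaks],
        "start": [iv.start for iv in peaks],
        "end": [iv.end for iv in peaks],
        "name": [iv.name or "." for iv in peaks],
        "width": peaks.widths(),
        "breadth_class": classification.classes,
    }
    if annotation is not None:
        rows["region"] = annotation.labels
        rows["region_detail"] = annotation.detail
    return pd.DataFrame(rows)
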