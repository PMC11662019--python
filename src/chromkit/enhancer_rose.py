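"""ROSE-style super-enhancer calling and miRNA-marking enrichment.

Enhancer constituents (H3K27ac peaks) within a stitching distance (default
12,500 bp, the ROSE default) are merged into stitched enhancers. Stitched
enhancers are ranked by background-subtracted signal; plotting scaled rank
against scaled signal gives the "hockey stick" curve, and the cutoff is the
first ascending point at which the discrete slope of the scaled curve exceeds
1. Everything above the cutoff is a super-enhancer (SE), everything below a
typical enhancer (TYE). SEs and TYEs are further stratified by width, and an
enhancer is miRNA-marked when at least one miRNA occupancy peak shares >=1
base with one of its constituent peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_intervals import GenomicInterval, IntervalSet, intersect, merge_intervals
from .stats_report import ContingencyTable, fisher_exact_2x2

SIZE_CLASSES = ("SE_broad", "SE_medium", "SE_narrow", "TYE_broad", "TYE_medium", "TYE_narrow")

# width strata in bp; lower bound inclusive, upper bound exclusive
SE_SIZE_BOUNDS = (2300, 3200)
TYE_SIZE_BOUNDS = (600, 900)


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its constituent peaks and SE call."""

    region: GenomicInterval
    constituents: list[GenomicInterval]
    signal: float = float("nan")
    rank: int | None = None
    is_super: bool = False
    size_class: str | None = None
    mirna_marked: bool = False

    @property
    def width(self) -> int:
        return self.region.width


@dataclass(frozen=True)
class SECutoff:
    """Signal cutoff separating SE from TYE on the scaled rank curve."""

    cutoff_signal: float
    cutoff_rank: int  # index of the first SE in ascending order; n if none


def stitch_enhancers(
    peaks: IntervalSet,
    stitch_distance: int = 12500,
    tss_windows: IntervalSet | None = None,
) -> list[StitchedEnhancer]:
    """Merge constituent peaks within ``stitch_distance`` bp into enhancers.

    When ``tss_windows`` is given, constituents lying fully inside a TSS
    window are excluded before stitching (the ROSE TSS exclusion; disabled by
    default, matching ROSE's default exclusion of 0).
    """
    if len(peaks) == 0:
        raise ValueError("cannot stitch an empty peak set")
    kept = list(peaks)
    if tss_windows is not None:
        windows = tss_windows.by_chrom()
        def fully_inside(iv: GenomicInterval) -> bool:
            return any(
                w.start <= iv.start and iv.end <= w.end
                for w in windows.get(iv.chrom, ())
            )
        kept = [iv for iv in kept if not fully_inside(iv)]
        if not kept:
            raise ValueError("no constituents left after TSS exclusion")
    kept_set = IntervalSet(kept, genome=peaks.genome)
    regions = merge_intervals(kept_set, max_gap=stitch_distance)
    enhancers = []
    by_chrom = kept_set.by_chrom()
    for region in regions.sorted():
        constituents = [
            iv for iv in by_chrom.get(region.chrom, ())
            if iv.start < region.end and region.start < iv.end
        ]
        enhancers.append(StitchedEnhancer(region=region, constituents=constituents))
    return enhancers


def rank_and_cutoff(
    enhancers: list[StitchedEnhancer],
    signal: Sequence[float],
    control: Sequence[float] | None = None,
) -> tuple[SECutoff, list[StitchedEnhancer]]:
    """Rank enhancers by net signal and call SEs at the hockey-stick cutoff.

    Net signal is max(signal - control, 0) when a background is given.
    Enhancers are sorted ascending by net signal; both axes are min-max scaled
    to [0, 1]; the cutoff is the net signal at the first ascending index whose
    discrete slope (adjacent points, span 1) exceeds 1. ``is_super`` is
    net signal > cutoff_signal, which makes the SE set invariant to affine
    rescaling of the signal vector. Rank 1 is the strongest enhancer.
    """
    if len(enhancers) < 3:
        raise ValueError("need >= 3 enhancers to locate a cutoff")
    sig = np.asarray(signal, dtype=float)
    if sig.shape != (len(enhancers),) or not np.all(np.isfinite(sig)):
        raise ValueError("signal must be one finite value per enhancer")
    if control is not None:
        ctl = np.asarray(control, dtype=float)
        net = np.maximum(sig - ctl, 0.0)
    else:
        net = sig.copy()
    if np.all(net == net[0]) and net[0] == 0.0:
        raise ValueError("degenerate ranking: all net signals are zero")
    order = np.argsort(net, kind="stable")
    net_sorted = net[order]
    cutoff_rank, cutoff_signal = _slope_cutoff(net_sorted)
    ordered = [enhancers[i] for i in order]
    n = len(ordered)
    for asc_idx, enh in enumerate(ordered):
        enh.signal = float(net_sorted[asc_idx])
        enh.rank = n - asc_idx  # rank 1 = strongest
        enh.is_super = bool(net_sorted[asc_idx] > cutoff_signal)
    return SECutoff(cutoff_signal=float(cutoff_signal), cutoff_rank=cutoff_rank), ordered


def _slope_cutoff(net_sorted: np.ndarray) -> tuple[int, float]:
    """First ascending index whose scaled discrete slope exceeds 1.

    Returns (cutoff_rank, cutoff_signal): cutoff_rank is the index of the
    first enhancer strictly above the cutoff signal (n if no slope exceeds 1,
    i.e. no SE is called).
    """
    n = len(net_sorted)
    rng = net_sorted[-1] - net_sorted[0]
    if rng == 0:
        return n, float(net_sorted[-1])
    x = np.arange(n) / (n - 1)
    y = (net_sorted - net_sorted[0]) / rng
    slopes = np.diff(y) / np.diff(x)
    above = np.flatnonzero(slopes > 1.0)
    if len(above) == 0:
        return n, float(net_sorted[-1])
    i = int(above[0])
    cutoff_signal = float(net_sorted[i])
    cutoff_rank = int(np.searchsorted(net_sorted, cutoff_signal, side="right"))
    return cutoff_rank, cutoff_signal


def classify_enhancer_size(enhancers: list[StitchedEnhancer]) -> list[StitchedEnhancer]:
    """Assign the six width strata (SE/TYE x broad/medium/narrow).

    SE: >=3.2 kb broad, [2.3, 3.2) kb medium, <2.3 kb narrow; TYE: >=0.9 kb
    broad, [0.6, 0.9) kb medium, <0.6 kb narrow. Lower bounds inclusive, upper
    bounds exclusive.
    """
    for enh in enhancers:
        lo, hi = SE_SIZE_BOUNDS if enh.is_super else TYE_SIZE_BOUNDS
        prefix = "SE" if enh.is_super else "TYE"
        w = enh.width
        if w >= hi:
            enh.size_class = f"{prefix}_broad"
        elif w >= lo:
            enh.size_class = f"{prefix}_medium"
        else:
            enh.size_class = f"{prefix}_narrow"
    return enhancers


def mark_by_mirna(
    enhancers: list[StitchedEnhancer],
    mirna_peaks: IntervalSet,
    on: str = "constituents",
) -> list[StitchedEnhancer]:
    """Flag enhancers with >=1 miRNA peak overlapping a constituent peak.

    The marking rule tests overlap against the constituent H3K27ac peaks, not
    the stitched gaps; set ``on="span"`` to test the full stitched region
    instead.
    """
    if on not in ("constituents", "span"):
        raise ValueError(f"unknown marking target {on!r}")
    for enh in enhancers:
        targets = enh.constituents if on == "constituents" else [enh.region]
        target_set = IntervalSet(targets)
        counts = intersect(target_set, mirna_peaks, mode="count")
        enh.mirna_marked = bool(np.any(counts > 0))
    return enhancers


def marking_enrichment_test(
    se_marked: int, se_total: int, tye_marked: int, tye_total: int
) -> tuple[float, float, float]:
    """Percent marked per enhancer class and the two-tailed Fisher p.

    Returns (pct_se_marked, pct_tye_marked, p).
    """
    if se_total <= 0 or tye_total <= 0:
        raise ValueError("enhancer class totals must be > 0")
    if se_marked > se_total or tye_marked > tye_total:
        raise ValueError("marked count exceeds class total")
    pct_se = 100.0 * se_marked / se_total
    pct_tye = 100.0 * tye_marked / tye_total
    p = fisher_exact_2x2(
        ContingencyTable(se_marked, se_total - se_marked, tye_marked, tye_total - tye_marked)
    )
    return pct_se, pct_tye, p


def enhancer_table(enhancers: list[StitchedEnhancer]) -> pd.DataFrame:
    """ROSE-like ranked output table (one row per stitched enhancer)."""
    return pd.DataFrame(
        {
            "chrom": [e.region.chrom for e in enhancers],
            "start": [e.region.start for e in enhancers],
            "end": [e.region.end for e in enhancers],
            "width": [e.width for e in enhancers],
            "n_constituents": [len(e.constituents) for e in enhancers],
            "signal": [e.signal for e in enhancers],
            "rank": [e.rank for e in enhancers],
            "is_super": [e.is_super for e in enhancers],
            "size_class": [e.size_class for e in enhancers],
            "mirna_marked": [e.mirna_marked for e in enhancers],
        }
    )


def hockey_stick_table(enhancers: list[StitchedEnhancer]) -> pd.DataFrame:
    """(rank, scaled signal, is_super) table for hockey-stick plotting."""
    ordered = sorted(enhancers, key=lambda e: e.signal)
    sig = np.array([e.signal for e in ordered])
    rng = np.ptp(sig)
    scaled = (sig - sig.min()) / rng if rng > 0 else np.zeros_like(sig)
    return pd.DataFrame(
        {
            "ascending_index": np.arange(len(ordered)),
            "rank": [e.rank for e in ordered],
            "signal": sig,
            "scaled_signal": scaled,
            "is_super": [e.is_super for e in ordered],
        }
    )
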