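"""Shared statistics: exact tests, expression quantification, differential
classes, aggregate signal profiles, z-score matrices and percentage reporting.

The two-tailed Fisher exact p-value follows the probability-mass convention:
the sum of hypergeometric probabilities of all tables with the observed
margins whose probability does not exceed that of the observed table (within a
relative tolerance of 1e-7). This is the common convention (R's fisher.test,
scipy) but differs from the "doubling" rule, hence it is documented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_intervals import GenomicInterval, IntervalSet

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 contingency table [[a, b], [c, d]] of non-negative counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact test on a 2x2 table.

    ``table`` may be a :class:`ContingencyTable` or any 2x2 array-like.
    Returns the probability-mass two-tailed p-value.
    """
    if not isinstance(table, ContingencyTable):
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValueError("fisher_exact_2x2 expects a 2x2 table")
        table = ContingencyTable(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(p, 1.0)


def rpkm(
    counts: np.ndarray | Sequence[float],
    lengths_kb: np.ndarray | Sequence[float],
    library_size: float,
) -> np.ndarray:
    """Reads per kilobase per million mapped reads.

    rpkm_g = counts_g / (lengths_kb_g * library_size / 1e6)
    """
    counts = np.asarray(counts, dtype=float)
    lengths_kb = np.asarray(lengths_kb, dtype=float)
    if np.any(lengths_kb <= 0):
        raise ValueError("gene lengths must be > 0 kb")
    if library_size <= 0:
        raise ValueError("library size must be > 0")
    return counts / (lengths_kb * (library_size / 1e6))


def classify_de(log2fc: np.ndarray | Sequence[float], cutoff: float = 0.58) -> np.ndarray:
    """Classify per-gene log2 fold changes as up / down / unchanged.

    Boundaries are inclusive: log2fc <= -cutoff -> down, >= +cutoff -> up.
    """
    fc = np.asarray(log2fc, dtype=float)
    if not np.all(np.isfinite(fc)):
        raise ValueError("log2 fold changes must be finite")
    out = np.full(fc.shape, "unchanged", dtype=object)
    out[fc <= -cutoff] = "down"
    out[fc >= cutoff] = "up"
    return out


def percent_of_total(part: int, total: int) -> float:
    """100*part/total rounded half-up to one decimal (reporting convention)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not (0 <= part <= total):
        raise ValueError("require 0 <= part <= total")
    pct = (Decimal(part) * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (config hook; the core figures apply no correction)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# piecewise-constant signal tracks (bedGraph in memory)


class TrackIndex:
    """Prefix-integral index over a piecewise-constant signal track.

    Segments (an :class:`IntervalSet` with scores, e.g. parsed bedGraph) must
    be non-overlapping per chromosome; uncovered bases have signal 0.
    """

    def __init__(self, track: IntervalSet):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in track.by_chrom().items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            vals = np.array([iv.score if iv.score is not None else 0.0 for iv in ivs])
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping track segments on {chrom}")
            cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
            self._chrom[chrom] = (starts, ends, vals, cum)

    def integral(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for each position."""
        pos = np.asarray(pos, dtype=np.int64)
        if chrom not in self._chrom:
            return np.zeros(pos.shape, dtype=float)
        starts, ends, vals, cum = self._chrom[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        i_clip = np.clip(i, 0, len(starts) - 1)
        inside = np.clip(pos - starts[i_clip], 0, ends[i_clip] - starts[i_clip])
        base = cum[np.clip(i, 0, len(starts) - 1)]
        out = np.where(i < 0, 0.0, base + vals[i_clip] * inside)
        return out

    def window_sum(self, chrom: str, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return self.integral(chrom, hi) - self.integral(chrom, lo)


def interval_signal(track: IntervalSet, intervals: IntervalSet | Sequence[GenomicInterval]) -> np.ndarray:
    """Summed signal (value x covered bp) of a track over each interval."""
    idx = TrackIndex(track)
    out = np.zeros(len(list(intervals)))
    for i, iv in enumerate(intervals):
        out[i] = idx.window_sum(iv.chrom, np.array([iv.start]), np.array([iv.end]))[0]
    return out


@dataclass
class AggregateProfile:
    """Mean signal per bin across anchors, bins offset relative to the anchor."""

    offsets: np.ndarray  # bin-center offsets, symmetric around 0
    means: np.ndarray
    n_anchors: int
    normalization: str = "RPMM"


def aggregate_profile(
    track: IntervalSet,
    anchors: Sequence[tuple[str, int, str]],
    half_window: int,
    bin: int,
    normalization: str = "RPMM",
) -> AggregateProfile:
    """Mean signal in uniform bins around reference points.

    ``anchors`` are (chrom, position, strand) triples; minus-strand anchors are
    flipped so that downstream of the anchor maps to positive offsets. ``bin``
    must divide ``2 * half_window``.
    """
    if bin < 1 or (2 * half_window) % bin != 0:
        raise ValueError("bin must be >= 1 and divide 2*half_window")
    n_bins = 2 * half_window // bin
    edges = np.arange(n_bins + 1) * bin - half_window
    idx = TrackIndex(track)
    acc = np.zeros(n_bins)
    for chrom, pos, strand in anchors:
        pts = pos + edges
        sums = idx.window_sum(chrom, np.maximum(pts[:-1], 0), np.maximum(pts[1:], 0))
        if strand == "-":
            sums = sums[::-1]
        acc += sums / bin
    means = acc / max(len(anchors), 1)
    offsets = (edges[:-1] + edges[1:]) / 2.0
    return AggregateProfile(offsets=offsets, means=means, n_anchors=len(anchors), normalization=normalization)


# ---------------------------------------------------------------------------
# z-scores and rank tests


def zscore_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores of a factors x classes table (sample sd, ddof=1)."""
    if values.shape[1] < 2:
        raise ValueError("need >=2 columns to z-score rows")
    sds = values.std(axis=1, ddof=1)
    zero = sds[sds == 0]
    if len(zero) > 0:
        raise ValueError(f"zero standard deviation for factor {zero.index[0]!r}")
    return values.sub(values.mean(axis=1), axis=0).div(sds, axis=0)


def rank_tests(x, y, kind: str = "wilcoxon_two_tailed") -> float:
    """Two-sample two-tailed tests used in the figure legends.

    ``t_two_tailed`` is the classic equal-variance two-sample t-test;
    ``wilcoxon_two_tailed`` is the Wilcoxon rank-sum (Mann-Whitney U), exact
    for <=25 combined tie-free observations, normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 observations per group")
    if kind == "t_two_tailed":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("degenerate variance in t-test")
        return float(sps.ttest_ind(x, y, equal_var=True).pvalue)
    if kind == "wilcoxon_two_tailed":
        combined = np.concatenate([x, y])
        has_ties = len(np.unique(combined)) < len(combined)
        if len(combined) <= 25 and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    raise ValueError(f"unknown test kind {kind!r}")
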