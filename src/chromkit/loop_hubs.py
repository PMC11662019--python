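"""Chromatin-interaction hubs, promoter-enhancer loop calling and response
clustering from HiChIP-style interaction pairs.

A hub is a fixed-resolution anchor bin together with the summed interaction
frequency of every pair touching it (default resolution 25 kb). Hubs with
total frequency >= 10 are retained and their frequencies normalized to the
retained-set mean, so normalized frequencies average to exactly 1. Loops are
pairs connecting a TSS +/- 2 kb promoter window to an H3K4me3 peak anchor;
condition-response profiles (log2 ratios to the control condition) of loop
loci are grouped by seeded k-means (default k=4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    intersect,
)
from .stats_report import percent_of_total

DEFAULT_RESOLUTION = 25_000
DEFAULT_MIN_HUB_FREQUENCY = 10


@dataclass(frozen=True)
class InteractionPair:
    """An unordered pair of interaction anchors with a contact frequency."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    frequency: int
    condition: str = "Ctrl"

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("interaction frequency must be >= 0")

    @property
    def is_self(self) -> bool:
        return (
            self.anchor1.chrom == self.anchor2.chrom
            and self.anchor1.start == self.anchor2.start
            and self.anchor1.end == self.anchor2.end
        )

    def key(self) -> tuple:
        k1 = (self.anchor1.chrom, self.anchor1.start, self.anchor1.end)
        k2 = (self.anchor2.chrom, self.anchor2.start, self.anchor2.end)
        return (k1, k2) if k1 <= k2 else (k2, k1)


@dataclass
class AnchorHub:
    """A fixed-resolution anchor bin with summed interaction frequency."""

    anchor: GenomicInterval
    total_frequency: int
    condition: str = "Ctrl"
    normalized_frequency: float | None = None


@dataclass
class LoopCall:
    """A promoter-to-distal loop with per-condition frequencies."""

    promoter_anchor: GenomicInterval
    distal_anchor: GenomicInterval
    gene_id: str
    frequency: dict[str, int]

    def locus(self) -> str:
        p, d = self.promoter_anchor, self.distal_anchor
        return f"{p.chrom}:{p.start}-{p.end}|{d.chrom}:{d.start}-{d.end}"

    def canonical_locus(self) -> str:
        return canonical_locus(self.promoter_anchor, self.distal_anchor)


def canonical_locus(a1: GenomicInterval, a2: GenomicInterval) -> str:
    """Orientation-independent locus key for an anchor pair."""
    k1 = (a1.chrom, a1.start, a1.end)
    k2 = (a2.chrom, a2.start, a2.end)
    (c1, s1, e1), (c2, s2, e2) = (k1, k2) if k1 <= k2 else (k2, k1)
    return f"{c1}:{s1}-{e1}|{c2}:{s2}-{e2}"


@dataclass
class ClusterResult:
    """k-means grouping of per-locus log2-ratio response profiles."""

    profiles: pd.DataFrame          # loci x non-control conditions, log2 ratios
    labels: np.ndarray              # cluster ids in 1..k
    centroids: pd.DataFrame         # k x conditions
    sizes: dict[int, int]
    seed: int


def read_pairs(path, condition: str = "Ctrl") -> list[InteractionPair]:
    """Read a 7-column BEDPE-like pairs file (chrom1 start1 end1 chrom2
    start2 end2 frequency)."""
    pairs: list[InteractionPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 7:
                raise ValueError(f"malformed pairs line {lineno} of {path}: need 7 columns")
            try:
                pairs.append(
                    InteractionPair(
                        anchor1=GenomicInterval(f[0], int(f[1]), int(f[2])),
                        anchor2=GenomicInterval(f[3], int(f[4]), int(f[5])),
                        frequency=int(f[6]),
                        condition=condition,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"malformed pairs line {lineno} of {path}: {exc}") from exc
    return pairs


def write_pairs(pairs: Sequence[InteractionPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.anchor1.chrom}\t{p.anchor1.start}\t{p.anchor1.end}\t"
                f"{p.anchor2.chrom}\t{p.anchor2.start}\t{p.anchor2.end}\t{p.frequency}\n"
            )


def write_washu_track(loops: Sequence[LoopCall], condition: str, path) -> None:
    """WashU/IGV-compatible loop track: anchor<TAB>anchor<TAB>score."""
    with open(path, "w") as fh:
        for lp in loops:
            p, d = lp.promoter_anchor, lp.distal_anchor
            fh.write(
                f"{p.chrom}:{p.start}-{p.end}\t{d.chrom}:{d.start}-{d.end}\t"
                f"{lp.frequency.get(condition, 0)}\n"
            )


def _snap(iv: GenomicInterval, resolution: int) -> GenomicInterval:
    b = (iv.start // resolution) * resolution
    return GenomicInterval(iv.chrom, b, b + resolution)


def bin_pairs(pairs: Iterable[InteractionPair], resolution: int = DEFAULT_RESOLUTION) -> list[InteractionPair]:
    """Snap anchors to resolution bins and sum frequencies of coincident pairs.

    Anchors map to [floor(start/res)*res, +res); binned pairs are canonically
    ordered so that (a1, a2) and (a2, a1) aggregate together. Total frequency
    is conserved.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    agg: dict[tuple, int] = {}
    conditions: dict[tuple, str] = {}
    for p in pairs:
        binned = InteractionPair(
            _snap(p.anchor1, resolution), _snap(p.anchor2, resolution),
            p.frequency, p.condition,
        )
        k = (p.condition,) + binned.key()
        agg[k] = agg.get(k, 0) + binned.frequency
        conditions[k] = p.condition
    out = []
    for k in sorted(agg):
        cond, (c1, s1, e1), (c2, s2, e2) = k[0], k[1], k[2]
        out.append(
            InteractionPair(
                GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2),
                agg[k], cond,
            )
        )
    return out


def build_hubs(pairs: Sequence[InteractionPair], condition: str | None = None) -> list[AnchorHub]:
    """One hub per distinct anchor bin; total = sum of frequencies of all
    pairs touching it (self-pairs counted once)."""
    totals: dict[tuple, int] = {}
    for p in pairs:
        if condition is not None and p.condition != condition:
            continue
        k1 = (p.anchor1.chrom, p.anchor1.start, p.anchor1.end)
        k2 = (p.anchor2.chrom, p.anchor2.start, p.anchor2.end)
        totals[k1] = totals.get(k1, 0) + p.frequency
        if k2 != k1:
            totals[k2] = totals.get(k2, 0) + p.frequency
    cond = condition if condition is not None else (pairs[0].condition if pairs else "Ctrl")
    return [
        AnchorHub(anchor=GenomicInterval(c, s, e), total_frequency=t, condition=cond)
        for (c, s, e), t in sorted(totals.items())
    ]


def filter_normalize_hubs(
    hubs: Sequence[AnchorHub], min_frequency: int = DEFAULT_MIN_HUB_FREQUENCY
) -> list[AnchorHub]:
    """Retain hubs with total frequency >= min_frequency and normalize to the
    retained-set mean (normalized frequencies average to exactly 1)."""
    kept = [h for h in hubs if h.total_frequency >= min_frequency]
    if not kept:
        raise ValueError("empty hub set after filtering")
    mean = float(np.mean([h.total_frequency for h in kept]))
    return [
        AnchorHub(
            anchor=h.anchor,
            total_frequency=h.total_frequency,
            condition=h.condition,
            normalized_frequency=h.total_frequency / mean,
        )
        for h in kept
    ]


def downsample_pairs(
    pairs: Sequence[InteractionPair], target_total: int, seed: int
) -> list[InteractionPair]:
    """Down-sample interaction events without replacement to a target total.

    Events are drawn across pairs proportionally to frequency (multivariate
    hypergeometric), so the summed output frequency equals ``target_total``
    exactly and the draw is reproducible per seed.
    """
    freqs = np.array([p.frequency for p in pairs], dtype=np.int64)
    total = int(freqs.sum())
    if target_total > total:
        raise ValueError(f"target_total {target_total} exceeds total frequency {total}")
    if target_total < 0:
        raise ValueError("target_total must be >= 0")
    rng = np.random.default_rng(seed)
    sampled = rng.multivariate_hypergeometric(freqs, target_total)
    return [
        InteractionPair(p.anchor1, p.anchor2, int(f), p.condition)
        for p, f in zip(pairs, sampled)
    ]


def _distance(p: InteractionPair) -> int:
    if p.anchor1.chrom != p.anchor2.chrom:
        return -1  # trans contact
    m1 = (p.anchor1.start + p.anchor1.end) // 2
    m2 = (p.anchor2.start + p.anchor2.end) // 2
    return abs(m2 - m1)


def _distance_bin(d: int, resolution: int) -> int:
    if d < 0:
        return -1
    return int(np.floor(np.log2(max(d // resolution, 1)))) if d > 0 else 0


def call_promoter_loops(
    pairs: Sequence[InteractionPair],
    h3k4me3_peaks: IntervalSet,
    genes: Sequence[GeneModel],
    tss_halfwidth: int = 2000,
    p_threshold: float | None = 0.01,
    resolution: int = DEFAULT_RESOLUTION,
) -> list[LoopCall]:
    """Call loops connecting a TSS window to an H3K4me3 peak anchor.

    A pair is a candidate when one anchor overlaps a TSS +/- ``tss_halfwidth``
    window and the other overlaps an H3K4me3 peak. Self-loops (identical
    anchor bins, or both anchors on the same TSS window) are excluded.
    Significance is a transparent frequency filter: the non-candidate pairs
    form a distance-matched background, and a candidate is retained when its
    best per-condition frequency exceeds the (1 - p_threshold) quantile of
    background frequencies in the same log2-spaced distance stratum
    (``p_threshold=None`` disables the filter; strata without background fall
    back to the global background quantile). Per-condition frequencies of the
    same anchor pair are aggregated into one :class:`LoopCall`.
    """
    promoters = IntervalSet([g.promoter(tss_halfwidth) for g in genes])
    # aggregate per unique anchor pair across conditions
    by_key: dict[tuple, dict[str, int]] = {}
    anchors_of: dict[tuple, tuple[GenomicInterval, GenomicInterval]] = {}
    for p in pairs:
        k = p.key()
        by_key.setdefault(k, {})
        by_key[k][p.condition] = by_key[k].get(p.condition, 0) + p.frequency
        if k not in anchors_of:
            (c1, s1, e1), (c2, s2, e2) = k
            anchors_of[k] = (GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2))

    keys = sorted(by_key)
    a1s = IntervalSet([anchors_of[k][0] for k in keys])
    a2s = IntervalSet([anchors_of[k][1] for k in keys])
    a1_prom = intersect(a1s, promoters, mode="count") > 0
    a2_prom = intersect(a2s, promoters, mode="count") > 0
    a1_peak = intersect(a1s, h3k4me3_peaks, mode="count") > 0
    a2_peak = intersect(a2s, h3k4me3_peaks, mode="count") > 0

    is_candidate = (a1_prom & a2_peak) | (a2_prom & a1_peak)

    # distance-stratified thresholds from the non-candidate background
    thresholds: dict[int, float] = {}
    global_threshold = 0.0
    if p_threshold is not None:
        if not (0 < p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        strata: dict[int, list[int]] = {}
        background_best: list[int] = []
        for i, k in enumerate(keys):
            if is_candidate[i]:
                continue
            a1, a2 = anchors_of[k]
            d = _distance(InteractionPair(a1, a2, 0))
            best = max(by_key[k].values())
            background_best.append(best)
            strata.setdefault(_distance_bin(d, resolution), []).append(best)
        q = 1.0 - p_threshold
        if background_best:
            global_threshold = float(np.quantile(background_best, q))
        for b, freqs in strata.items():
            thresholds[b] = float(np.quantile(freqs, q))

    prom_by_chrom = promoters.by_chrom()

    def shared_tss_window(a1: GenomicInterval, a2: GenomicInterval) -> bool:
        if a1.chrom != a2.chrom:
            return False
        return any(a1.overlaps(w) and a2.overlaps(w) for w in prom_by_chrom.get(a1.chrom, ()))

    def gene_for(anchor: GenomicInterval) -> str:
        for g in genes:
            if g.chrom == anchor.chrom and anchor.overlaps(g.promoter(tss_halfwidth)):
                return g.gene_id
        return "."

    loops: list[LoopCall] = []
    for i, k in enumerate(keys):
        a1, a2 = anchors_of[k]
        if a1.chrom == a2.chrom and a1.start == a2.start and a1.end == a2.end:
            continue
        if a1_prom[i] and a2_peak[i]:
            prom, distal = a1, a2
        elif a2_prom[i] and a1_peak[i]:
            prom, distal = a2, a1
        else:
            continue
        if shared_tss_window(a1, a2):
            continue
        if p_threshold is not None:
            d = _distance(InteractionPair(a1, a2, 0))
            thr = thresholds.get(_distance_bin(d, resolution), global_threshold)
            if max(by_key[k].values()) <= thr:
                continue
        loops.append(
            LoopCall(
                promoter_anchor=prom,
                distal_anchor=distal,
                gene_id=gene_for(prom),
                frequency=dict(sorted(by_key[k].items())),
            )
        )
    return loops


def loop_frequency_table(loops: Sequence[LoopCall], conditions: Sequence[str]) -> pd.DataFrame:
    """Loci x condition frequency table from loop calls (missing counts -> 0)."""
    data = {
        c: [lp.frequency.get(c, 0) for lp in loops] for c in conditions
    }
    df = pd.DataFrame(data, index=[lp.locus() for lp in loops])
    df.index.name = "locus"
    return df


def cluster_interaction_profiles(
    freq_by_condition: pd.DataFrame,
    k: int = 4,
    pseudocount: float = 1.0,
    seed: int = 0,
    ctrl: str = "Ctrl",
    standardize: bool = False,
) -> ClusterResult:
    """Seeded k-means on per-locus log2-ratio response profiles.

    profile(locus, c) = log2((freq_c + pseudocount) / (freq_ctrl + pseudocount))
    for every non-control condition c. Cluster ids are 1..k. Profiles are
    clustered raw by default; per-locus standardization is available as a
    config switch.
    """
    from sklearn.cluster import KMeans

    if ctrl not in freq_by_condition.columns:
        raise ValueError(f"control condition {ctrl!r} missing from table")
    if len(freq_by_condition) < k:
        raise ValueError(f"need >= {k} loci to form {k} clusters")
    others = [c for c in freq_by_condition.columns if c != ctrl]
    base = freq_by_condition[ctrl].to_numpy(dtype=float) + pseudocount
    profiles = pd.DataFrame(
        {
            c: np.log2((freq_by_condition[c].to_numpy(dtype=float) + pseudocount) / base)
            for c in others
        },
        index=freq_by_condition.index,
    )
    X = profiles.to_numpy()
    if standardize:
        sd = X.std(axis=1, ddof=0, keepdims=True)
        X = (X - X.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X) + 1
    centroids = pd.DataFrame(km.cluster_centers_, columns=others, index=np.arange(1, k + 1))
    sizes = {int(c): int(np.sum(labels == c)) for c in range(1, k + 1)}
    return ClusterResult(
        profiles=profiles, labels=labels, centroids=centroids, sizes=sizes, seed=seed
    )


def count_hub_overlap_with_peaks(
    hubs: Sequence[AnchorHub], peaks: IntervalSet
) -> tuple[int, int, float]:
    """Partition hubs by >=1-base overlap with any peak.

    Returns (n_overlapping, n_total, percentage).
    """
    if not hubs:
        raise ValueError("no hubs to partition")
    anchor_set = IntervalSet([h.anchor for h in hubs])
    counts = intersect(anchor_set, peaks, mode="count")
    n_overlap = int(np.sum(counts > 0))
    return n_overlap, len(hubs), percent_of_total(n_overlap, len(hubs))


def hub_table(hubs: Sequence[AnchorHub]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [h.anchor.chrom for h in hubs],
            "start": [h.anchor.start for h in hubs],
            "end": [h.anchor.end for h in hubs],
            "condition": [h.condition for h in hubs],
            "total_frequency": [h.total_frequency for h in hubs],
            "normalized_frequency": [h.normalized_frequency for h in hubs],
        }
    )
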