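"""G-quadruplex propensity scoring and degenerate motif scanning.

Per-base G4 propensity follows the G4Hunter scheme: every G in a maximal
G-run of length L scores +min(L, 4), every C in a C-run scores -min(L, 4),
and A/T/U/N score 0. A sliding arithmetic mean over a window (default 25 nt,
the published genome-scan default) gives window scores, and maximal runs of
windows at or above a threshold (default 1.2) are merged into candidate G4
regions. The module also scans sequences for IUPAC degenerate motifs such as
the expanded miRNA nuclear-shuttling motif AKYACCWUUUGRUWA (U and T are
equivalent throughout).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .genome_intervals import GenomicInterval, IntervalSet, intersect

DEFAULT_WINDOW = 25
DEFAULT_THRESHOLD = 1.2

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SHUTTLING_MOTIF = "AKYACCWUUUGRUWA"


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate nucleotide pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern.upper() if c not in IUPAC_SETS]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in motif {self.pattern!r}")

    @property
    def length(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        # character classes over {A,C,G,T}; an N in the *sequence* never matches
        body = "".join(
            f"[{IUPAC_SETS[c]}]" if len(IUPAC_SETS[c]) > 1 else IUPAC_SETS[c]
            for c in self.pattern.upper()
        )
        return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


@dataclass
class G4Profile:
    """Per-base run scores and per-window means for one sequence."""

    sequence_id: str
    base_scores: np.ndarray
    window_scores: np.ndarray
    window: int


@dataclass(frozen=True)
class G4Region:
    """A called G4 candidate region with its mean and peak window score."""

    interval: GenomicInterval
    mean_score: float
    max_window_score: float


def _clean_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)} in sequence")
    return s


def _run_lengths(mask: np.ndarray) -> np.ndarray:
    """Length of the maximal run each position belongs to."""
    n = len(mask)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(mask.astype(np.int8)) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    lengths = (ends - starts).astype(np.int64)
    return np.repeat(lengths, lengths)


def g4_base_scores(seq: str) -> np.ndarray:
    """Per-base G4 propensity scores in [-4, 4] (run scores capped at 4)."""
    s = _clean_sequence(seq)
    arr = np.frombuffer(s.encode("ascii"), dtype="S1")
    is_g = arr == b"G"
    is_c = arr == b"C"
    runs_g = _run_lengths(is_g)
    runs_c = _run_lengths(is_c)
    scores = np.zeros(len(arr), dtype=np.int64)
    scores[is_g] = np.minimum(runs_g[is_g], 4)
    scores[is_c] = -np.minimum(runs_c[is_c], 4)
    return scores


def g4_window_scores(base_scores: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sliding arithmetic mean of base scores over each window.

    Sequences shorter than the window yield a single mean over the whole
    sequence.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    base_scores = np.asarray(base_scores, dtype=float)
    n = len(base_scores)
    if n == 0:
        return np.zeros(0)
    if n < window:
        return np.array([base_scores.mean()])
    cs = np.concatenate([[0.0], np.cumsum(base_scores)])
    return (cs[window:] - cs[:-window]) / window


def g4_profile(seq: str, window: int = DEFAULT_WINDOW, sequence_id: str = "seq") -> G4Profile:
    base = g4_base_scores(seq)
    return G4Profile(
        sequence_id=sequence_id,
        base_scores=base,
        window_scores=g4_window_scores(base, window),
        window=window,
    )


def call_g4_regions(
    profile: G4Profile,
    threshold: float = DEFAULT_THRESHOLD,
    genome_offset: GenomicInterval | None = None,
) -> list[G4Region]:
    """Merge maximal runs of windows scoring >= threshold into G4 regions.

    A region spans from the first qualifying window's start to the last
    qualifying window's end; its mean score is recomputed over the merged
    span. ``genome_offset`` lifts coordinates onto a chromosome.
    """
    ws = profile.window_scores
    n_bases = len(profile.base_scores)
    if len(ws) == 0:
        return []
    chrom = genome_offset.chrom if genome_offset is not None else profile.sequence_id
    shift = genome_offset.start if genome_offset is not None else 0
    qual = ws >= threshold
    if not np.any(qual):
        return []
    idx = np.flatnonzero(qual)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [len(idx) - 1]])
    regions: list[G4Region] = []
    win = profile.window if n_bases >= profile.window else n_bases
    for rs, re_ in zip(run_starts, run_ends):
        first, last = int(idx[rs]), int(idx[re_])
        lo = first
        hi = min(last + win, n_bases)
        span_scores = profile.base_scores[lo:hi]
        regions.append(
            G4Region(
                interval=GenomicInterval(chrom, shift + lo, shift + hi),
                mean_score=float(np.mean(span_scores)),
                max_window_score=float(np.max(ws[first : last + 1])),
            )
        )
    return regions


def g4_regions_to_intervals(regions: list[G4Region]) -> IntervalSet:
    """G4 regions as a BED-writable interval set (mean score in the score column)."""
    return IntervalSet(
        [
            GenomicInterval(
                r.interval.chrom, r.interval.start, r.interval.end,
                name="G4", score=round(r.mean_score, 4),
            )
            for r in regions
        ]
    )


def filter_peaks_by_g4(peaks: IntervalSet, g4: list[G4Region] | IntervalSet) -> IntervalSet:
    """Retain peaks overlapping >=1 called G4 region."""
    if not isinstance(g4, IntervalSet):
        g4 = IntervalSet([r.interval for r in g4])
    return intersect(peaks, g4, mode="report_a")


def reverse_complement(seq: str) -> str:
    return _clean_sequence(seq).translate(_COMPLEMENT)[::-1]


def scan_iupac_motif(
    seq: str,
    motif: IUPACMotif | str,
    both_strands: bool = False,
) -> list[tuple[int, str]]:
    """All 0-based offsets where the motif matches, with the matching strand.

    Overlapping matches are reported. When ``both_strands`` is set, the
    reverse complement is scanned as well and hits are mapped back to
    plus-strand coordinates of the leftmost matching base.
    """
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    s = _clean_sequence(seq)
    pat = motif.regex()
    hits = [(m.start(), "+") for m in pat.finditer(s)]
    if both_strands:
        rc = reverse_complement(s)
        L = len(s)
        hits += [(L - m.start() - motif.length, "-") for m in pat.finditer(rc)]
    return sorted(hits)


def motif_hits_to_intervals(
    hits: list[tuple[int, str]], motif: IUPACMotif | str, chrom: str
) -> IntervalSet:
    """Motif hits as BED6-writable intervals carrying the strand."""
    if isinstance(motif, str):
        motif = IUPACMotif(motif)
    return IntervalSet(
        [
            GenomicInterval(chrom, pos, pos + motif.length, name=motif.pattern, strand=strand)
            for pos, strand in hits
        ]
    )


def read_fasta(path) -> dict[str, str]:
    """Read a (plain, uncompressed) FASTA file into a dict of sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
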