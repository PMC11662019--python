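"""Core genomic-interval algebra and readers/writers for interval-shaped formats.

All coordinates are 0-based half-open (BED convention). Two intervals overlap
iff they share at least one base; bookended intervals ([0,10) and [10,20)) do
not overlap but do merge at ``max_gap=0``. Strand is carried but ignored by
overlap operations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")

_BED_FAMILY = {"bed", "narrowpeak", "broadpeak", "bedgraph"}
_FORMATS = _BED_FAMILY | {"tsv"}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span with optional name/score/strand.

    Columns beyond the first six of a BED-family record are preserved verbatim
    in ``extra``.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >=1 base (strand-agnostic)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sort_key(self) -> tuple:
        # ties broken by (start, end, name) for deterministic output
        return (self.chrom, self.start, self.end, self.name or "")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` with an optional genome.

    When a genome (chrom -> length mapping) is attached, every interval must
    fit inside its chromosome.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome: dict[str, int] | None = dict(genome) if genome is not None else None
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom not in self.genome:
                    raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > self.genome[iv.chrom]:
                    raise ValueError(
                        f"interval {iv} extends past end of {iv.chrom} "
                        f"({self.genome[iv.chrom]} bp)"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return sorted(self.intervals, key=GenomicInterval.sort_key) == sorted(
            other.intervals, key=GenomicInterval.sort_key
        )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=GenomicInterval.sort_key), genome=self.genome
        )

    def widths(self) -> np.ndarray:
        return np.array([iv.width for iv in self.intervals], dtype=np.int64)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        for ivs in out.values():
            ivs.sort(key=GenomicInterval.sort_key)
        return out


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is <= ``max_gap`` bp (bedtools-merge semantics).

    Overlapping or bookended intervals always merge at ``max_gap=0``; the union
    of covered bases is preserved exactly at ``max_gap=0``. Output intervals
    are pairwise non-overlapping per chromosome and carry no name/score/strand.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[GenomicInterval] = []
    for chrom, ivs in sorted(iset.by_chrom().items()):
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(merged, genome=iset.genome)


def _overlap_counts(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Per-a-interval count of overlapping b-intervals (order of ``a`` kept)."""
    by_b = b.by_chrom()
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_b.items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.sort(np.array([iv.end for iv in ivs], dtype=np.int64))
        starts_ends[chrom] = (starts, ends)
    counts = np.zeros(len(a), dtype=np.int64)
    for i, iv in enumerate(a):
        if iv.chrom not in starts_ends:
            continue
        starts, ends = starts_ends[iv.chrom]
        # b overlaps a  <=>  b.start < a.end  and  b.end > a.start
        n_start_ok = int(np.searchsorted(starts, iv.end, side="left"))
        n_end_too_small = int(np.searchsorted(ends, iv.start, side="right"))
        counts[i] = n_start_ok - n_end_too_small
    return counts


def intersect(a: IntervalSet, b: IntervalSet, mode: str = "report_a"):
    """Interval overlap in three modes (half-open >=1-shared-base semantics).

    ``report_a``
        each a-interval overlapping >=1 b-interval, reported exactly once
        (bedtools intersect -wa -u).
    ``exclude_a``
        a-intervals with zero overlap (bedtools intersect -wa -v; the
        blacklist-removal contract).
    ``count``
        per-a-interval overlap counts as a numpy array.
    """
    if mode not in ("report_a", "exclude_a", "count"):
        raise ValueError(f"unknown intersect mode {mode!r}")
    counts = _overlap_counts(a, b)
    if mode == "count":
        return counts
    if mode == "report_a":
        keep = counts > 0
    else:
        keep = counts == 0
    return IntervalSet(
        [iv for iv, k in zip(a, keep) if k], genome=a.genome
    )


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """A gene with TSS, strand and exon structure.

    ``tss`` is a 0-based position; for minus-strand genes it is the rightmost
    transcribed base. Exons must be non-overlapping after sorting and the TSS
    must lie within the exon span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        exs = sorted(self.exons, key=GenomicInterval.sort_key)
        for e1, e2 in zip(exs, exs[1:]):
            if e2.start < e1.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", tuple(exs))
        span_lo = exs[0].start
        span_hi = exs[-1].end
        if not (span_lo <= self.tss < span_hi):
            raise ValueError(
                f"gene {self.gene_id}: TSS {self.tss} outside exon span "
                f"[{span_lo},{span_hi})"
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end,
            name=self.gene_id, strand=self.strand,
        )

    @property
    def length_kb(self) -> float:
        """Summed exon length in kb."""
        return sum(e.width for e in self.exons) / 1000.0

    def promoter(self, halfwidth: int = 2000, chrom_length: int | None = None) -> GenomicInterval:
        """TSS +/- ``halfwidth`` window, clipped to [0, chrom_length)."""
        lo = max(0, self.tss - halfwidth)
        hi = self.tss + halfwidth
        if chrom_length is not None:
            hi = min(hi, chrom_length)
        return GenomicInterval(self.chrom, lo, hi, name=self.gene_id, strand=self.strand)


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a TSV with header gene_id/chrom/strand/tss/exons.

    ``exons`` is a comma-separated list of ``start-end`` half-open spans.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("gene_id", "chrom", "strand", "tss", "exons"):
            if col not in idx:
                raise ValueError(f"gene model file {path} missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                chrom = fields[idx["chrom"]]
                exons = tuple(
                    GenomicInterval(chrom, int(s), int(e))
                    for s, e in (tok.split("-") for tok in fields[idx["exons"]].split(","))
                )
                genes.append(
                    GeneModel(
                        gene_id=fields[idx["gene_id"]],
                        chrom=chrom,
                        strand=fields[idx["strand"]],
                        tss=int(fields[idx["tss"]]),
                        exons=exons,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"malformed gene model at line {lineno} of {path}: {exc}") from exc
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texons\n")
        for g in genes:
            exons = ",".join(f"{e.start}-{e.end}" for e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{exons}\n")


# ---------------------------------------------------------------------------
# readers / writers


def _parse_score(tok: str) -> float | None:
    if tok in (".", ""):
        return None
    return float(tok)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "."
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def read_intervals(path, format: str = "bed", genome: Mapping[str, int] | None = None) -> IntervalSet:
    """Read an interval file as an :class:`IntervalSet`.

    Formats: ``bed`` (BED3-BED6+), ``narrowPeak``/``broadPeak`` (columns beyond
    6 kept as opaque payload), ``bedgraph`` (column 4 mapped to score), and
    ``tsv`` (header with at least chrom/start/end). Comment, ``track`` and
    ``browser`` lines are skipped. Malformed lines raise with their line number.
    """
    fmt = format.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown interval format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        if fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for col in ("chrom", "start", "end"):
                if col not in idx:
                    raise ValueError(f"TSV {path} missing column {col!r}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                try:
                    iv = GenomicInterval(
                        chrom=f[idx["chrom"]],
                        start=int(f[idx["start"]]),
                        end=int(f[idx["end"]]),
                        name=(f[idx["name"]] if f[idx["name"]] not in (".", "") else None)
                        if "name" in idx else None,
                        score=_parse_score(f[idx["score"]]) if "score" in idx else None,
                        strand=f[idx["strand"]] if "strand" in idx else ".",
                    )
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"malformed line {lineno} of {path}: {exc}") from exc
                intervals.append(iv)
        else:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if (
                    not stripped
                    or stripped.startswith("#")
                    or stripped.startswith("track")
                    or stripped.startswith("browser")
                ):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 3:
                    raise ValueError(
                        f"malformed line {lineno} of {path}: expected >=3 tab-separated columns"
                    )
                try:
                    start, end = int(f[1]), int(f[2])
                    if start >= end:
                        raise ValueError(f"start >= end at line {lineno}")
                    if fmt == "bedgraph":
                        iv = GenomicInterval(
                            f[0], start, end,
                            score=float(f[3]) if len(f) > 3 else None,
                        )
                    else:
                        iv = GenomicInterval(
                            chrom=f[0],
                            start=start,
                            end=end,
                            name=(f[3] or None) if len(f) > 3 and f[3] != "." else None,
                            score=_parse_score(f[4]) if len(f) > 4 else None,
                            strand=f[5] if len(f) > 5 else ".",
                            extra=tuple(f[6:]),
                        )
                except ValueError as exc:
                    if "start >= end" in str(exc):
                        raise ValueError(f"start >= end at line {lineno} of {path}") from None
                    raise ValueError(f"malformed line {lineno} of {path}: {exc}") from exc
                intervals.append(iv)
    return IntervalSet(intervals, genome=genome)


def write_intervals(iset: IntervalSet, path, format: str = "bed") -> None:
    """Write an interval set; round-trips with :func:`read_intervals` for
    BED3/BED6 content."""
    fmt = format.lower()
    if fmt not in ("bed", "tsv", "bedgraph"):
        raise ValueError(f"unknown output format {format!r}")
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("chrom\tstart\tend\tname\tscore\tstrand\n")
            for iv in iset:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\n"
                )
        elif fmt == "bedgraph":
            for iv in iset:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt_score(iv.score)}\n")
        else:
            for iv in iset:
                fields = [iv.chrom, str(iv.start), str(iv.end)]
                if iv.name is not None or iv.score is not None or iv.strand != "." or iv.extra:
                    fields += [iv.name or ".", _fmt_score(iv.score), iv.strand]
                    fields += list(iv.extra)
                fh.write("\t".join(fields) + "\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"malformed chrom.sizes line {lineno} of {path}")
            genome[f[0]] = int(f[1])
    return genome


def write_chrom_sizes(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
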