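"""Seeded synthetic-data generator with planted ground truth.

Produces a toy genome and every pipeline input — histone-mark peak sets with a
planted breadth mixture, clustered enhancer constituents forming true
super-enhancers, miRNA occupancy peaks marking SEs more often than typical
enhancers, G-quadruplex-forming tracts, condition-dependent promoter-SE
interaction pairs with four planted response archetypes, and an expression
count table with planted up/down regulation — alongside truth tables that
recovery tests read instead of re-deriving truth from generation code.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning, so every emitted file is byte-identical across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    intersect,
    write_chrom_sizes,
    write_gene_models,
    write_intervals,
)
from .g4_motif import write_fasta


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic inputs.

    Defaults are chosen once to emulate the statistical structure the
    analysis assumes: a three-mode peak-width mixture with the top quartile
    broad, dense high-signal constituent clusters against sparse weak
    singletons, SE-biased miRNA marking (25% vs 4%), four loop-response
    archetypes at |log2 ratio| = 2 with sigma = 0.1 noise, and a 73.5% / 26.5%
    down/up split among differentially expressed genes.
    """

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gc_content: float = 0.42
    # genes
    n_genes: int = 300
    # H3K4me3 breadth mixture (narrow, medium, broad)
    n_h3k4me3: int = 2000
    breadth_fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    breadth_width_means: tuple[float, float, float] = (1200.0, 2350.0, 3600.0)
    breadth_width_sds: tuple[float, float, float] = (150.0, 90.0, 280.0)
    # enhancers
    n_se: int = 60
    n_tye: int = 400
    constituents_per_se_mean: float = 5.0
    constituent_width_mean: float = 900.0
    constituent_width_sd: float = 120.0
    constituent_gap_min: int = 200
    constituent_gap_max: int = 2200
    tye_width_mean: float = 750.0
    tye_width_sd: float = 150.0
    se_signal_per_bp: float = 15.0
    tye_signal_per_bp: float = 3.0
    signal_noise_cv: float = 0.10
    control_signal_per_bp: float = 0.5
    # miRNA occupancy
    mirna_marking_prob_se: float = 0.25
    mirna_marking_prob_tye: float = 0.04
    mirna_peak_width: int = 300
    mirna_promoter_prob: float = 0.30
    # G4 tracts
    g4_tract_rate_per_mb: float = 10.0
    g4_loop_min: int = 1
    g4_loop_max: int = 3
    # interactions
    loop_conditions: tuple[str, ...] = ("Ctrl", "TGFB1", "TGFB1_LOF")
    ctrl_condition: str = "Ctrl"
    n_loops_per_cluster: int = 50
    # per-cluster (log2 TGFB1/Ctrl, log2 LOF/Ctrl) response multipliers
    loop_log2_multipliers: tuple[tuple[float, float], ...] = (
        (2.0, 2.0),
        (2.0, -2.0),
        (0.0, 0.0),
        (-2.0, -2.0),
    )
    loop_noise_sd: float = 0.1
    loop_baseline_mean: float = 30.0
    loop_baseline_dispersion: float = 10.0
    n_background_pairs: int = 2000
    background_pair_mean: float = 6.0
    background_pair_dispersion: float = 5.0
    bin_resolution: int = 25_000
    # expression
    de_fraction: float = 0.30
    de_down_share: float = 0.735
    de_log2fc: float = 1.2
    tgfb1_up_log2fc: float = 1.0
    expr_mean_log: float = float(np.log(300.0))
    expr_mean_log_sd: float = 1.0
    expr_dispersion: float = 100.0

    def __post_init__(self) -> None:
        if abs(sum(self.breadth_fractions) - 1.0) > 1e-9:
            raise ValueError("breadth fractions must sum to 1")
        for p in (
            self.mirna_marking_prob_se, self.mirna_marking_prob_tye,
            self.mirna_promoter_prob, self.gc_content, self.de_fraction,
            self.de_down_share,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if not (1 <= self.g4_loop_min <= self.g4_loop_max):
            raise ValueError("G4 loop bounds must satisfy 1 <= min <= max")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one deterministic sub-stream."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class PlantedTruth:
    """Ground-truth labels matching the emitted synthetic files."""

    h3k4me3_classes: pd.DataFrame | None = None     # peak name, width, class
    se_regions: IntervalSet | None = None
    enhancer_marking: pd.DataFrame | None = None    # unit, kind, coords, marked
    g4_tracts: IntervalSet | None = None
    loop_clusters: pd.DataFrame | None = None       # locus, gene_id, cluster
    de_classes: pd.DataFrame | None = None          # gene_id, class, log2fc


def _negative_binomial(rng: np.random.Generator, mean, dispersion, size=None) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (size) parameter."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _place_blocks(
    rng: np.random.Generator,
    block_lengths: Sequence[int],
    genome: Mapping[str, int],
    gap_min: int,
    gap_max: int,
) -> list[tuple[str, int]]:
    """Tile blocks left-to-right across chromosomes with random gaps.

    Blocks are split across chromosomes proportionally to length; raises if a
    chromosome cannot host its share.
    """
    chroms = list(genome)
    total = sum(genome.values())
    n = len(block_lengths)
    shares = [int(round(n * genome[c] / total)) for c in chroms]
    shares[-1] = n - sum(shares[:-1])
    out: list[tuple[str, int]] = []
    i = 0
    for chrom, share in zip(chroms, shares):
        lengths = np.asarray(block_lengths[i : i + share], dtype=np.int64)
        i += share
        if len(lengths) == 0:
            continue
        gaps = rng.integers(gap_min, gap_max + 1, size=len(lengths))
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths[:-1])])
        ends = starts + lengths
        if ends[-1] > genome[chrom]:
            raise ValueError(
                f"genome too small: {chrom} needs {ends[-1]} bp for "
                f"{len(lengths)} blocks but has {genome[chrom]}"
            )
        out.extend((chrom, int(s)) for s in starts)
    return out


# ---------------------------------------------------------------------------
# genome + G4 tracts


def _g4_tract(rng: np.random.Generator, cfg: SyntheticConfig) -> str:
    loops = rng.integers(cfg.g4_loop_min, cfg.g4_loop_max + 1, size=3)
    parts = ["GGG"]
    for l in loops:
        parts.append("".join(rng.choice(["A", "T"], size=l)))
        parts.append("GGG")
    return "".join(parts)


def generate_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], IntervalSet]:
    """Random background sequence with planted G4 tracts.

    Returns (sequences, planted tract coordinates). Tracts have the form
    (GGG N_1..loop_max) x 4 with A/T loops, planted at ``g4_tract_rate_per_mb``
    and recorded exactly.
    """
    rng = cfg.rng(0)
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    seqs: dict[str, str] = {}
    tracts: list[GenomicInterval] = []
    for chrom, length in cfg.genome.items():
        arr = rng.choice(bases, size=length, p=probs)
        n_tracts = int(round(cfg.g4_tract_rate_per_mb * length / 1e6))
        if n_tracts > 0:
            # non-overlapping, well-separated tract positions
            positions = np.sort(
                rng.choice(length // 1000 - 1, size=n_tracts, replace=False)
            ) * 1000
            for j, pos in enumerate(positions):
                tract = _g4_tract(rng, cfg)
                arr[pos : pos + len(tract)] = np.frombuffer(tract.encode(), dtype="S1")
                tracts.append(
                    GenomicInterval(chrom, int(pos), int(pos) + len(tract), name=f"g4_{chrom}_{j}")
                )
        seqs[chrom] = arr.tobytes().decode("ascii")
    return seqs, IntervalSet(tracts, genome=cfg.genome)


# ---------------------------------------------------------------------------
# gene models


def generate_genes(cfg: SyntheticConfig) -> list[GeneModel]:
    """Evenly spaced genes with alternating strand and random exon structure."""
    rng = cfg.rng(1)
    genes: list[GeneModel] = []
    chroms = list(cfg.genome)
    per_chrom = [cfg.n_genes // len(chroms)] * len(chroms)
    per_chrom[-1] += cfg.n_genes - sum(per_chrom)
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        spacing = cfg.chrom_length // (n + 1)
        for j in range(n):
            anchor = spacing * (j + 1)
            n_exons = int(rng.integers(3, 9))
            exon_lens = rng.integers(150, 1200, size=n_exons)
            intron_lens = rng.integers(500, 3000, size=n_exons - 1)
            strand = "+" if gid % 2 == 0 else "-"
            starts = [anchor]
            for el, il in zip(exon_lens[:-1], intron_lens):
                starts.append(starts[-1] + int(el) + int(il))
            exons = tuple(
                GenomicInterval(chrom, s, s + int(el))
                for s, el in zip(starts, exon_lens)
            )
            tss = exons[0].start if strand == "+" else exons[-1].end - 1
            genes.append(GeneModel(f"gene_{gid:04d}", chrom, strand, tss, exons))
            gid += 1
    return genes


# ---------------------------------------------------------------------------
# peaks, enhancers, miRNA occupancy, signal


def generate_peaks(cfg: SyntheticConfig, genes: Sequence[GeneModel] | None = None):
    """H3K4me3 / H3K27ac / miRNA peak sets, the signal track and truth labels.

    Returns a dict with IntervalSets ``h3k4me3``, ``h3k27ac``, ``mirna``,
    ``signal`` (bedGraph-like), ``control_signal``, plus ``truth``
    (:class:`PlantedTruth` with breadth classes, true SE regions and marking
    flags).
    """
    rng = cfg.rng(2)
    genome = cfg.genome
    if genes is None:
        genes = generate_genes(cfg)

    # --- H3K4me3 peaks: widths from the breadth mixture, exact class counts
    n = cfg.n_h3k4me3
    counts = [int(round(f * n)) for f in cfg.breadth_fractions]
    counts[-1] = n - sum(counts[:-1])
    class_names = np.repeat(["narrow", "medium", "broad"], counts)
    widths = np.concatenate(
        [
            np.maximum(
                np.round(rng.normal(m, s, size=c)).astype(np.int64), 200
            )
            for c, m, s in zip(counts, cfg.breadth_width_means, cfg.breadth_width_sds)
        ]
    )
    order = rng.permutation(n)
    class_names, widths = class_names[order], widths[order]
    placements = _place_blocks(rng, widths, genome, 500, 2500)
    k4_peaks = IntervalSet(
        [
            GenomicInterval(chrom, start, start + int(w), name=f"k4me3_{i:05d}")
            for i, ((chrom, start), w) in enumerate(zip(placements, widths))
        ],
        genome=genome,
    )
    k4_truth = pd.DataFrame(
        {
            "name": [iv.name for iv in k4_peaks],
            "chrom": [iv.chrom for iv in k4_peaks],
            "start": [iv.start for iv in k4_peaks],
            "end": [iv.end for iv in k4_peaks],
            "width": widths,
            "breadth_class": class_names,
        }
    )

    # --- enhancer units: SE constituent clusters and TYE singletons
    units = ["SE"] * cfg.n_se + ["TYE"] * cfg.n_tye
    units = [units[i] for i in rng.permutation(len(units))]
    unit_layouts: list[tuple[str, list[tuple[int, int]]]] = []  # kind, [(offset, width)]
    unit_lengths: list[int] = []
    for kind in units:
        if kind == "SE":
            k = max(2, int(rng.poisson(cfg.constituents_per_se_mean)))
            ws = np.maximum(
                np.round(rng.normal(cfg.constituent_width_mean, cfg.constituent_width_sd, size=k)).astype(int),
                150,
            )
            gaps = rng.integers(cfg.constituent_gap_min, cfg.constituent_gap_max + 1, size=k - 1)
            offs, cur = [], 0
            for j, w in enumerate(ws):
                offs.append((cur, int(w)))
                if j < k - 1:
                    cur += int(w) + int(gaps[j])
            span = offs[-1][0] + offs[-1][1]
        else:
            w = max(150, int(round(rng.normal(cfg.tye_width_mean, cfg.tye_width_sd))))
            offs = [(0, w)]
            span = w
        unit_layouts.append((kind, offs))
        unit_lengths.append(span)
    unit_pos = _place_blocks(rng, unit_lengths, genome, 13_000, 17_000)

    constituents: list[GenomicInterval] = []
    signal_segments: list[GenomicInterval] = []
    unit_records = []
    se_regions: list[GenomicInterval] = []
    unit_constituents: list[list[GenomicInterval]] = []
    se_idx = 0
    for u, ((kind, offs), (chrom, start)) in enumerate(zip(unit_layouts, unit_pos)):
        amp_mean = cfg.se_signal_per_bp if kind == "SE" else cfg.tye_signal_per_bp
        ivs = []
        for j, (off, w) in enumerate(offs):
            iv = GenomicInterval(chrom, start + off, start + off + w, name=f"enh_{u:04d}_{j}")
            ivs.append(iv)
            amp = max(0.1, rng.normal(amp_mean, amp_mean * cfg.signal_noise_cv))
            signal_segments.append(
                GenomicInterval(chrom, iv.start, iv.end, score=round(float(amp), 4))
            )
        constituents.extend(ivs)
        unit_constituents.append(ivs)
        span = GenomicInterval(chrom, ivs[0].start, ivs[-1].end, name=f"unit_{u:04d}")
        if kind == "SE":
            se_regions.append(
                GenomicInterval(chrom, span.start, span.end, name=f"true_se_{se_idx:03d}")
            )
            se_idx += 1
        unit_records.append(
            {"unit": f"unit_{u:04d}", "kind": kind, "chrom": chrom,
             "start": span.start, "end": span.end}
        )

    # --- miRNA occupancy: marking peaks + promoter peaks clear of enhancers
    mirna: list[GenomicInterval] = []
    marked_flags = []
    for (kind, _), ivs in zip(unit_layouts, unit_constituents):
        p = cfg.mirna_marking_prob_se if kind == "SE" else cfg.mirna_marking_prob_tye
        marked = bool(rng.random() < p)
        marked_flags.append(marked)
        if marked:
            c = ivs[int(rng.integers(len(ivs)))]
            pos = int(rng.integers(c.start, c.end))
            end = min(pos + cfg.mirna_peak_width, genome[c.chrom])
            mirna.append(GenomicInterval(c.chrom, pos, end, name=f"mir9_{len(mirna):04d}"))
    for rec, m in zip(unit_records, marked_flags):
        rec["mirna_marked"] = m
    constituent_set = IntervalSet(constituents, genome=genome)
    if cfg.mirna_promoter_prob > 0:
        # promoter occupancy peaks, kept clear of enhancer constituents so
        # they cannot perturb the planted marking probabilities
        promoters = IntervalSet([g.promoter(2000, genome[g.chrom]) for g in genes])
        prom_hits = intersect(promoters, constituent_set, mode="count")
        for g, n_hit in zip(genes, prom_hits):
            if n_hit == 0 and rng.random() < cfg.mirna_promoter_prob:
                lo = max(0, g.tss - cfg.mirna_peak_width // 2)
                mirna.append(
                    GenomicInterval(g.chrom, lo, lo + cfg.mirna_peak_width,
                                    name=f"mir9_{len(mirna):04d}")
                )

    truth = PlantedTruth(
        h3k4me3_classes=k4_truth,
        se_regions=IntervalSet(se_regions, genome=genome),
        enhancer_marking=pd.DataFrame(unit_records),
        g4_tracts=None,
    )
    control = IntervalSet(
        [
            GenomicInterval(chrom, 0, length, score=cfg.control_signal_per_bp)
            for chrom, length in genome.items()
        ],
        genome=genome,
    )
    return {
        "h3k4me3": k4_peaks,
        "h3k27ac": constituent_set,
        "mirna": IntervalSet(sorted(mirna, key=GenomicInterval.sort_key), genome=genome),
        "signal": IntervalSet(sorted(signal_segments, key=GenomicInterval.sort_key), genome=genome),
        "control_signal": control,
        "genes": list(genes),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# interactions


def generate_interactions(
    cfg: SyntheticConfig,
    genes: Sequence[GeneModel],
    se_regions: IntervalSet,
):
    """Per-condition interaction pairs with planted response archetypes.

    Promoter-SE pairs get negative-binomial baseline frequencies and one of
    four response archetypes (per-condition log2 multipliers from the config);
    distance-decay background pairs are added on top. Returns
    (pairs_by_condition, truth table).
    """
    from .loop_hubs import InteractionPair, canonical_locus

    rng = cfg.rng(3)
    res = cfg.bin_resolution
    conditions = list(cfg.loop_conditions)
    ctrl = cfg.ctrl_condition
    others = [c for c in conditions if c != ctrl]
    k = len(cfg.loop_log2_multipliers)
    n_resp = cfg.n_loops_per_cluster * k

    se_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in se_regions:
        se_by_chrom.setdefault(iv.chrom, []).append(iv)

    chosen_genes = [genes[i] for i in rng.choice(len(genes), size=n_resp, replace=False)]
    pairs: dict[str, list[InteractionPair]] = {c: [] for c in conditions}
    truth_rows = []
    for i, g in enumerate(chosen_genes):
        cluster = i // cfg.n_loops_per_cluster + 1
        mults = cfg.loop_log2_multipliers[cluster - 1]
        tss_bin = (g.tss // res) * res
        anchor1 = GenomicInterval(g.chrom, tss_bin, tss_bin + res)
        ses = se_by_chrom.get(g.chrom, [])
        anchor2 = None
        for _ in range(20):
            se = ses[int(rng.integers(len(ses)))]
            mid = (se.start + se.end) // 2
            se_bin = (mid // res) * res
            if se_bin != tss_bin:
                anchor2 = GenomicInterval(g.chrom, se_bin, se_bin + res)
                break
        if anchor2 is None:
            continue
        base = max(5, int(_negative_binomial(rng, cfg.loop_baseline_mean, cfg.loop_baseline_dispersion)))
        freqs = {ctrl: base}
        for c, m in zip(others, mults):
            noisy = m + rng.normal(0.0, cfg.loop_noise_sd)
            freqs[c] = max(0, int(round(base * 2.0**noisy)))
        for c in conditions:
            pairs[c].append(InteractionPair(anchor1, anchor2, freqs[c], c))
        truth_rows.append(
            {
                "locus": canonical_locus(anchor1, anchor2),
                "gene_id": g.gene_id,
                "cluster": cluster,
                **{f"freq_{c}": freqs[c] for c in conditions},
            }
        )

    # distance-decay + uniform background pairs
    chroms = list(cfg.genome)
    n_bins = cfg.chrom_length // res
    for b in range(cfg.n_background_pairs):
        chrom = chroms[int(rng.integers(len(chroms)))]
        b1 = int(rng.integers(n_bins))
        if rng.random() < 0.5:
            d = 1 + int(rng.geometric(0.1))
        else:
            d = 1 + int(rng.integers(n_bins - 1))
        b2 = min(b1 + d, n_bins - 1)
        if b2 == b1:
            continue
        a1 = GenomicInterval(chrom, b1 * res, (b1 + 1) * res)
        a2 = GenomicInterval(chrom, b2 * res, (b2 + 1) * res)
        mean = cfg.background_pair_mean * (1.0 + 4.0 / d)
        for c in conditions:
            f = int(_negative_binomial(rng, mean, cfg.background_pair_dispersion))
            pairs[c].append(InteractionPair(a1, a2, f, c))

    truth = pd.DataFrame(truth_rows)
    return pairs, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(cfg: SyntheticConfig, genes: Sequence[GeneModel]):
    """Negative-binomial count table with planted up/down regulation.

    A ``de_fraction`` of genes is planted as differentially expressed between
    control and loss-of-function, split ``de_down_share`` down vs up at
    +/- ``de_log2fc``; TGFB1 additionally up-regulates the planted-down genes
    (the TGFB1-responsive, miRNA-dependent set). Returns (counts DataFrame
    indexed by gene with one column per condition, truth table).
    """
    rng = cfg.rng(4)
    n = len(genes)
    n_de = int(round(cfg.de_fraction * n))
    n_down = int(round(cfg.de_down_share * n_de))
    de_idx = rng.choice(n, size=n_de, replace=False)
    classes = np.full(n, "unchanged", dtype=object)
    classes[de_idx[:n_down]] = "down"
    classes[de_idx[n_down:]] = "up"

    base_mean = np.exp(rng.normal(cfg.expr_mean_log, cfg.expr_mean_log_sd, size=n))
    lfc = np.zeros(n)
    lfc[classes == "down"] = -cfg.de_log2fc
    lfc[classes == "up"] = cfg.de_log2fc
    tgfb = np.where(classes == "down", cfg.tgfb1_up_log2fc, 0.0)

    counts = pd.DataFrame(
        {
            "Ctrl": _negative_binomial(rng, base_mean, cfg.expr_dispersion),
            "TGFB1": _negative_binomial(rng, base_mean * 2.0**tgfb, cfg.expr_dispersion),
            "LOF": _negative_binomial(rng, base_mean * 2.0**lfc, cfg.expr_dispersion),
        },
        index=pd.Index([g.gene_id for g in genes], name="gene_id"),
    )
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "de_class": classes,
            "planted_log2fc": lfc,
            "length_kb": [g.length_kb for g in genes],
        }
    )
    return counts, truth


# ---------------------------------------------------------------------------
# one-call generation with files on disk


def generate_all(cfg: SyntheticConfig, outdir, with_genome: bool = True) -> dict:
    """Generate every pipeline input under ``outdir`` with a truth/ directory.

    Returns the in-memory objects as well (keyed like the emitted files).
    """
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    genes = generate_genes(cfg)
    data = generate_peaks(cfg, genes)
    pairs, loop_truth = generate_interactions(cfg, genes, data["truth"].se_regions)
    counts, de_truth = generate_expression(cfg, genes)
    data["truth"].loop_clusters = loop_truth
    data["truth"].de_classes = de_truth

    write_gene_models(genes, out / "genes.tsv")
    write_intervals(data["h3k4me3"], out / "h3k4me3_peaks.bed")
    write_intervals(data["h3k27ac"], out / "h3k27ac_peaks.bed")
    write_intervals(data["mirna"], out / "mir9_peaks.bed")
    write_intervals(data["signal"], out / "h3k27ac_signal.bedgraph", format="bedgraph")
    write_intervals(data["control_signal"], out / "control_signal.bedgraph", format="bedgraph")
    write_chrom_sizes(cfg.genome, out / "chrom.sizes")
    from .loop_hubs import write_pairs

    for cond, plist in pairs.items():
        write_pairs(plist, out / f"pairs_{cond}.bedpe")
    counts.to_csv(out / "expression_counts.tsv", sep="\t")

    if with_genome:
        seqs, tracts = generate_genome(cfg)
        data["truth"].g4_tracts = tracts
        write_fasta(seqs, out / "genome.fa")
        write_intervals(tracts, out / "truth" / "g4_tracts.bed")
        data["genome_sequences"] = seqs

    truth = data["truth"]
    truth.h3k4me3_classes.to_csv(out / "truth" / "h3k4me3_classes.tsv", sep="\t", index=False)
    write_intervals(truth.se_regions, out / "truth" / "se_regions.bed")
    truth.enhancer_marking.to_csv(out / "truth" / "enhancer_marking.tsv", sep="\t", index=False)
    loop_truth.to_csv(out / "truth" / "loop_clusters.tsv", sep="\t", index=False)
    de_truth.to_csv(out / "truth" / "de_classes.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=list)

    data["pairs"] = pairs
    data["expression"] = counts
    return data


def audit_truth(outdir) -> dict[str, bool]:
    """Self-audit: verify that emitted files are consistent with the truth.

    Checks that truth breadth widths match the emitted H3K4me3 peaks, that
    marking flags equal an overlap recomputation against the emitted miRNA
    peaks, and that planted G4 tracts (if present) contain the planted G-runs.
    Raises AssertionError on any inconsistency.
    """
    from .genome_intervals import read_intervals
    from .g4_motif import read_fasta

    out = Path(outdir)
    checks: dict[str, bool] = {}

    k4 = read_intervals(out / "h3k4me3_peaks.bed")
    k4_truth = pd.read_csv(out / "truth" / "h3k4me3_classes.tsv", sep="\t")
    widths = {iv.name: iv.width for iv in k4}
    checks["h3k4me3_widths"] = all(
        widths[r["name"]] == r["width"] for _, r in k4_truth.iterrows()
    )

    marking = pd.read_csv(out / "truth" / "enhancer_marking.tsv", sep="\t")
    constituents = read_intervals(out / "h3k27ac_peaks.bed")
    mirna = read_intervals(out / "mir9_peaks.bed")
    by_unit: dict[str, list[GenomicInterval]] = {}
    for iv in constituents:
        unit = "unit_" + iv.name.split("_")[1]
        by_unit.setdefault(unit, []).append(iv)
    ok = True
    for _, rec in marking.iterrows():
        ivs = IntervalSet(by_unit[rec["unit"]])
        overlap = bool(np.any(intersect(ivs, mirna, mode="count") > 0))
        ok &= overlap == bool(rec["mirna_marked"])
    checks["mirna_marking"] = ok

    g4_bed = out / "truth" / "g4_tracts.bed"
    if g4_bed.exists() and (out / "genome.fa").exists():
        seqs = read_fasta(out / "genome.fa")
        tracts = read_intervals(g4_bed)
        checks["g4_tracts"] = all(
            seqs[iv.chrom][iv.start : iv.end].count("GGG") >= 4 for iv in tracts
        )

    for name, passed in checks.items():
        if not passed:
            raise AssertionError(f"synthetic self-audit failed: {name}")
    return checks
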