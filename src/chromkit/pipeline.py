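"""End-to-end orchestration of the analysis stages.

``run_all`` executes: synthetic generation (optional) -> breadth
classification -> SE calling + miRNA marking -> G4 scoring and filtering ->
hubs / loops / response clustering -> expression statistics, writing
per-stage TSVs and a JSON report with every headline statistic. When planted
truth is available (synthetic runs), recovery metrics are added to the
report.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    domain_breadth as db,
    enhancer_rose as er,
    g4_motif as g4,
    genome_intervals as gi,
    loop_hubs as lh,
    stats_report as sr,
    synthetic_data as sd,
)

log = logging.getLogger("chromkit")


@dataclass
class PipelineConfig:
    """Flat configuration for a full pipeline run.

    When ``simulate`` is true, all inputs are generated under
    ``outdir/simulated`` with the given seed; otherwise the ``*_path`` fields
    must point at existing files.
    """

    outdir: str = "chromkit_run"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is false)
    h3k4me3_path: str | None = None
    h3k27ac_path: str | None = None
    mirna_path: str | None = None
    signal_path: str | None = None
    control_signal_path: str | None = None
    genes_path: str | None = None
    genome_fasta_path: str | None = None
    pairs_paths: dict = field(default_factory=dict)  # condition -> path
    expression_path: str | None = None
    # stage parameters
    promoter_halfwidth: int = 2000
    stitch_distance: int = 12500
    g4_window: int = 25
    g4_threshold: float = 1.2
    bin_resolution: int = 25_000
    min_hub_frequency: int = 10
    loop_p_threshold: float = 0.01
    kmeans_k: int = 4
    ctrl_condition: str = "Ctrl"
    de_cutoff: float = 0.58
    de_ctrl_column: str = "Ctrl"
    de_treatment_column: str = "LOF"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _require(path, what: str) -> Path:
    if path is None:
        raise ValueError(f"missing input path for {what}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input for {what} not found: {p}")
    return p


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the JSON-able report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    truth: sd.PlantedTruth | None = None
    if config.simulate:
        log.info("stage=simulate seed=%d outdir=%s", config.seed, out / "simulated")
        cfg = sd.SyntheticConfig(
            seed=config.seed,
            ctrl_condition=config.ctrl_condition,
            bin_resolution=config.bin_resolution,
        )
        sim = sd.generate_all(cfg, out / "simulated")
        truth = sim["truth"]
        simdir = out / "simulated"
        config.h3k4me3_path = str(simdir / "h3k4me3_peaks.bed")
        config.h3k27ac_path = str(simdir / "h3k27ac_peaks.bed")
        config.mirna_path = str(simdir / "mir9_peaks.bed")
        config.signal_path = str(simdir / "h3k27ac_signal.bedgraph")
        config.control_signal_path = str(simdir / "control_signal.bedgraph")
        config.genes_path = str(simdir / "genes.tsv")
        config.genome_fasta_path = str(simdir / "genome.fa")
        config.pairs_paths = {
            c: str(simdir / f"pairs_{c}.bedpe") for c in cfg.loop_conditions
        }
        config.expression_path = str(simdir / "expression_counts.tsv")

    genes = gi.read_gene_models(_require(config.genes_path, "gene models"))

    # ---- breadth stage -----------------------------------------------------
    log.info("stage=breadth peaks=%s", config.h3k4me3_path)
    k4 = gi.read_intervals(_require(config.h3k4me3_path, "H3K4me3 peaks"))
    thresholds = db.compute_breadth_thresholds(k4.widths())
    classification = db.classify_breadth(k4, thresholds)
    annotation = db.annotate_region(k4, genes, config.promoter_halfwidth)
    table = db.classification_table(k4, classification, annotation)
    table.to_csv(out / "breadth_classes.tsv", sep="\t", index=False)
    breadth_stats = {
        "n_peaks": len(k4),
        "q2_bp": thresholds.q2,
        "q3_bp": thresholds.q3,
        "class_counts": classification.counts(),
        "region_counts": annotation.counts(),
    }
    if truth is not None:
        planted = truth.h3k4me3_classes.set_index("name")["breadth_class"]
        called = pd.Series(classification.classes, index=[iv.name for iv in k4])
        acc = float((called == planted.reindex(called.index)).mean())
        breadth_stats["breadth_class_accuracy"] = acc
    report["stages"]["breadth"] = breadth_stats

    # ---- super-enhancer stage ---------------------------------------------
    log.info("stage=se_call peaks=%s stitch=%d", config.h3k27ac_path, config.stitch_distance)
    k27 = gi.read_intervals(_require(config.h3k27ac_path, "H3K27ac peaks"))
    mirna = gi.read_intervals(_require(config.mirna_path, "miRNA peaks"))
    track = gi.read_intervals(_require(config.signal_path, "signal track"), format="bedgraph")
    enhancers = er.stitch_enhancers(k27, config.stitch_distance)
    regions = gi.IntervalSet([e.region for e in enhancers])
    signal = sr.interval_signal(track, regions)
    control = None
    if config.control_signal_path:
        ctl_track = gi.read_intervals(config.control_signal_path, format="bedgraph")
        control = sr.interval_signal(ctl_track, regions)
    cutoff, enhancers = er.rank_and_cutoff(enhancers, signal, control)
    enhancers = er.classify_enhancer_size(enhancers)
    enhancers = er.mark_by_mirna(enhancers, mirna)
    se = [e for e in enhancers if e.is_super]
    tye = [e for e in enhancers if not e.is_super]
    pct_se, pct_tye, p_marking = er.marking_enrichment_test(
        sum(e.mirna_marked for e in se), len(se),
        sum(e.mirna_marked for e in tye), len(tye),
    )
    er.enhancer_table(enhancers).to_csv(out / "enhancers_ranked.tsv", sep="\t", index=False)
    er.enhancer_table(se).to_csv(out / "super_enhancers.tsv", sep="\t", index=False)
    er.hockey_stick_table(enhancers).to_csv(out / "hockey_stick.tsv", sep="\t", index=False)
    se_stats = {
        "n_enhancers": len(enhancers),
        "n_se": len(se),
        "n_tye": len(tye),
        "cutoff_signal": cutoff.cutoff_signal,
        "pct_se_mirna_marked": pct_se,
        "pct_tye_mirna_marked": pct_tye,
        "marking_fisher_p": p_marking,
        "size_class_counts": {
            c: sum(e.size_class == c for e in enhancers) for c in er.SIZE_CLASSES
        },
    }
    if truth is not None:
        true_se = truth.se_regions
        called_regions = gi.IntervalSet([e.region for e in se])
        tp = len(gi.intersect(called_regions, true_se, mode="report_a"))
        recalled = len(gi.intersect(true_se, called_regions, mode="report_a"))
        se_stats["se_precision"] = tp / len(called_regions) if len(called_regions) else 0.0
        se_stats["se_recall"] = recalled / len(true_se) if len(true_se) else 0.0
    report["stages"]["se_call"] = se_stats

    # ---- G4 stage ----------------------------------------------------------
    log.info("stage=g4 window=%d threshold=%.2f", config.g4_window, config.g4_threshold)
    seqs = g4.read_fasta(_require(config.genome_fasta_path, "genome FASTA"))
    regions_called: list[g4.G4Region] = []
    motif_hits = 0
    for chrom, seq in sorted(seqs.items()):
        profile = g4.g4_profile(seq, window=config.g4_window, sequence_id=chrom)
        regions_called.extend(g4.call_g4_regions(profile, config.g4_threshold))
        motif_hits += len(g4.scan_iupac_motif(seq, g4.SHUTTLING_MOTIF, both_strands=True))
    g4_set = g4.g4_regions_to_intervals(regions_called)
    gi.write_intervals(g4_set, out / "g4_regions.bed")
    mirna_in_g4 = g4.filter_peaks_by_g4(mirna, g4_set)
    g4_stats = {
        "n_g4_regions": len(regions_called),
        "n_shuttling_motif_hits": motif_hits,
        "pct_mirna_peaks_in_g4": sr.percent_of_total(len(mirna_in_g4), len(mirna))
        if len(mirna) else 0.0,
    }
    if truth is not None and truth.g4_tracts is not None:
        recovered = len(gi.intersect(truth.g4_tracts, g4_set, mode="report_a"))
        g4_stats["g4_tract_recovery"] = recovered / len(truth.g4_tracts)
    report["stages"]["g4"] = g4_stats

    # ---- loops / hubs stage -------------------------------------------------
    log.info("stage=loops resolution=%d", config.bin_resolution)
    if not config.pairs_paths:
        raise ValueError("missing input path for interaction pairs")
    binned: dict[str, list[lh.InteractionPair]] = {}
    for cond, path in config.pairs_paths.items():
        raw = lh.read_pairs(_require(path, f"pairs ({cond})"), condition=cond)
        binned[cond] = lh.bin_pairs(raw, config.bin_resolution)
    totals = {c: sum(p.frequency for p in ps) for c, ps in binned.items()}
    target = min(totals.values())
    downsampled = {
        c: lh.downsample_pairs(ps, target, seed=config.seed)
        for c, ps in sorted(binned.items())
    }
    hubs = {}
    hub_counts = {}
    for cond, ps in sorted(binned.items()):
        h = lh.build_hubs(ps, condition=cond)
        h = lh.filter_normalize_hubs(h, config.min_hub_frequency)
        hubs[cond] = h
        hub_counts[cond] = len(h)
    lh.hub_table([h for hs in hubs.values() for h in hs]).to_csv(
        out / "hubs.tsv", sep="\t", index=False
    )
    ctrl = config.ctrl_condition
    n_ov, n_tot, pct_hub_mirna = lh.count_hub_overlap_with_peaks(hubs[ctrl], mirna)
    all_pairs = [p for ps in downsampled.values() for p in ps]
    loops = lh.call_promoter_loops(
        all_pairs, k4, genes,
        tss_halfwidth=config.promoter_halfwidth,
        p_threshold=config.loop_p_threshold,
        resolution=config.bin_resolution,
    )
    conditions = sorted(binned)
    freq_table = lh.loop_frequency_table(loops, conditions)
    cluster = lh.cluster_interaction_profiles(
        freq_table, k=config.kmeans_k, seed=config.seed, ctrl=ctrl
    )
    assign = pd.DataFrame(
        {"locus": freq_table.index, "cluster": cluster.labels}
    )
    assign.to_csv(out / "loop_clusters.tsv", sep="\t", index=False)
    for cond in conditions:
        lh.write_washu_track(loops, cond, out / f"loops_{cond}.washu.txt")
    loop_stats = {
        "hub_counts": hub_counts,
        "pct_hubs_mirna": pct_hub_mirna,
        "downsample_target": int(target),
        "n_loops": len(loops),
        "cluster_sizes": cluster.sizes,
    }
    if truth is not None and truth.loop_clusters is not None and len(loops) >= config.kmeans_k:
        from sklearn.metrics import adjusted_rand_score

        planted = truth.loop_clusters.set_index("locus")["cluster"]
        called_loci = pd.Series(
            cluster.labels, index=[lp.canonical_locus() for lp in loops]
        )
        common = planted.index.intersection(called_loci.index)
        if len(common) > 0:
            loop_stats["cluster_agreement"] = float(
                adjusted_rand_score(planted.loc[common], called_loci.loc[common])
            )
            loop_stats["n_truth_loops_recovered"] = int(len(common))
    report["stages"]["loops"] = loop_stats

    # ---- expression stage ----------------------------------------------------
    log.info("stage=expression counts=%s", config.expression_path)
    counts = pd.read_csv(
        _require(config.expression_path, "expression counts"), sep="\t", index_col=0
    )
    lengths = pd.Series({g.gene_id: g.length_kb for g in genes})
    lengths = lengths.reindex(counts.index)
    rpkms = pd.DataFrame(
        {
            c: sr.rpkm(counts[c].to_numpy(), lengths.to_numpy(), counts[c].sum())
            for c in counts.columns
        },
        index=counts.index,
    )
    log2fc = np.log2(
        (rpkms[config.de_treatment_column] + 1.0) / (rpkms[config.de_ctrl_column] + 1.0)
    )
    de = sr.classify_de(log2fc.to_numpy(), cutoff=config.de_cutoff)
    de_table = pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc.to_numpy(), "de_class": de}
    )
    de_table.to_csv(out / "expression_de.tsv", sep="\t", index=False)
    n_down = int(np.sum(de == "down"))
    n_up = int(np.sum(de == "up"))
    n_aff = n_down + n_up
    expr_stats = {
        "n_genes": len(counts),
        "n_affected": n_aff,
        "n_down": n_down,
        "n_up": n_up,
        "pct_down_of_affected": sr.percent_of_total(n_down, n_aff) if n_aff else 0.0,
        "pct_up_of_affected": sr.percent_of_total(n_up, n_aff) if n_aff else 0.0,
    }
    if truth is not None and truth.de_classes is not None:
        planted = truth.de_classes.set_index("gene_id")["de_class"]
        called = pd.Series(de, index=counts.index)
        both = planted.reindex(called.index)
        affected = both != "unchanged"
        if affected.any():
            expr_stats["de_recovery"] = float((called[affected] == both[affected]).mean())
    report["stages"]["expression"] = expr_stats

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("report=%s", out / "report.json")
    return report
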