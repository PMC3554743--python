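"""End-to-end orchestration of the small-RNA analysis stages.

Each stage reads its inputs from, and writes plain-text outputs (TSV, FASTA,
GFF3, BED, JSON) into, a single run directory, so every stage is also
independently runnable and testable from files.  ``run_pipeline`` chains
simulate -> clean -> annotate -> quantify -> novel -> de -> targets ->
enrich and renders a consolidated Markdown report.  Given the same config
and seed, reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, de, novel, reads, simulate, targets
from .io import (
    ensure_dir,
    read_fasta,
    read_gff3,
    read_tag_fasta,
    write_bed,
    write_fasta,
    write_tag_fasta,
    iter_fastq,
)


@dataclass
class RunConfig:
    """Every stage's parameters, each with a working default."""

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    adapter: str = simulate.ADAPTER_3P
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_quality: int = 20
    min_len: int = 18
    max_len: int = 30
    kmer: int = 12
    isomir_window: int = 2
    merge_distance: int = 10
    flank_up: int = 70
    flank_down: int = 70
    mfe_threshold: float = novel.MFE_THRESHOLD
    min_tpm: float = novel.TPM_THRESHOLD
    require_both_samples: bool = True
    dicer_threshold: float = 0.7
    min_cluster_reads: int = 3
    alpha: float = 0.05
    min_fold: float = 2.0
    floor_tpm: float = 0.01
    min_support: int = 3
    energy_threshold: float = targets.DUPLEX_ENERGY_THRESHOLD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim_cfg = simulate.config_from_dict(data.pop("sim", {}))
        cfg = cls(sim=sim_cfg, **data)
        if "seed" in data:
            cfg.sim.seed = cfg.seed
        return cfg


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing input {outdir / name}"
            )


def stage_simulate(cfg: RunConfig, outdir) -> None:
    outdir = ensure_dir(outdir)
    sim = simulate.build_genome(cfg.sim)
    sim.write(outdir)
    simulate.simulate_libraries(sim, outdir)


def stage_clean(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "clean", "lib_A.fastq", "lib_B.fastq")
    results = {}
    for lib in "AB":
        records = iter_fastq(outdir / f"lib_{lib}.fastq")
        results[lib] = reads.clean_reads(
            records,
            adapter=cfg.adapter,
            min_overlap=cfg.min_overlap,
            max_mismatch_rate=cfg.max_mismatch_rate,
            min_quality=cfg.min_quality,
            min_len=cfg.min_len,
            max_len=cfg.max_len,
        )
    tags = reads.collapse_tags(results["A"].inserts, results["B"].inserts)
    tags.to_csv(outdir / "tags.tsv", sep="\t", index=False)
    write_tag_fasta(tags, outdir / "tags.fa")
    summaries = reads.summarize_libraries(tags)
    qc = {
        lib: {
            "counters": results[lib].counters,
            "total_clean_reads": summaries[lib].total_clean_reads,
            "unique_common": summaries[lib].unique_common,
            "unique_specific": summaries[lib].unique_specific,
            "total_common": summaries[lib].total_common,
            "total_specific": summaries[lib].total_specific,
        }
        for lib in "AB"
    }
    with open(outdir / "qc_clean.json", "w") as fh:
        json.dump(qc, fh, sort_keys=True, indent=1)
    hist = pd.DataFrame(
        {
            "length": summaries["A"].length_histogram.index,
            "reads_a": summaries["A"].length_histogram.values,
            "reads_b": summaries["B"].length_histogram.values,
        }
    )
    hist.to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)
    for lib in "AB":
        summaries[lib].first_base_by_length.to_csv(
            outdir / f"first_base_by_length_{lib}.tsv", sep="\t"
        )


def _load_totals(outdir: Path) -> tuple[int, int]:
    with open(outdir / "qc_clean.json") as fh:
        qc = json.load(fh)
    return qc["A"]["total_clean_reads"], qc["B"]["total_clean_reads"]


def _load_genome(outdir: Path) -> str:
    genome = read_fasta(outdir / "genome.fa")
    return next(iter(genome.values()))


def stage_annotate(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "annotate", "tags.tsv", "genome.fa", "features.gff3")
    tags = pd.read_csv(outdir / "tags.tsv", sep="\t")
    genome = read_fasta(outdir / "genome.fa")
    features = read_gff3(outdir / "features.gff3")
    hits = annotate.map_tags(tags, genome, k=cfg.kmer)
    annotated = annotate.assign_categories(tags, hits, features)
    annotated.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    annotate.category_summary(annotated).to_csv(
        outdir / "category_counts.tsv", sep="\t", index=False
    )
    annotate.chromosome_strand_table(annotated, hits).to_csv(
        outdir / "chrom_strand.tsv", sep="\t", index=False
    )
    totals = _load_totals(outdir)
    with open(outdir / "qc_rrna.json", "w") as fh:
        json.dump(annotate.qc_rrna_fraction(annotated, totals), fh, sort_keys=True, indent=1)


def stage_quantify(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "quantify", "annotation.tsv", "features.gff3")
    annotated = pd.read_csv(outdir / "annotation.tsv", sep="\t", keep_default_na=False)
    features = read_gff3(outdir / "features.gff3")
    totals = _load_totals(outdir)
    mature, precursor = annotate.quantify_known(
        annotated, features, totals, isomir_window=cfg.isomir_window
    )
    mature.to_csv(outdir / "known_mirna_counts.tsv", sep="\t", index=False)
    precursor.to_csv(outdir / "precursor_counts.tsv", sep="\t", index=False)


def stage_novel(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "novel", "annotation.tsv", "genome.fa")
    annotated = pd.read_csv(outdir / "annotation.tsv", sep="\t", keep_default_na=False)
    genome_map = read_fasta(outdir / "genome.fa")
    genome = next(iter(genome_map.values()))
    tags = annotated[["sequence", "count_a", "count_b"]]
    hits = annotate.map_tags(tags, genome_map, k=cfg.kmer)
    clusters = novel.cluster_unannotated(annotated, hits, cfg.merge_distance)
    totals = _load_totals(outdir)
    table = novel.call_novel(
        clusters,
        genome,
        totals,
        mfe_threshold=cfg.mfe_threshold,
        min_tpm=cfg.min_tpm,
        require_both_samples=cfg.require_both_samples,
        dicer_threshold=cfg.dicer_threshold,
        min_reads=cfg.min_cluster_reads,
        flank_up=cfg.flank_up,
        flank_down=cfg.flank_down,
    )
    table.to_csv(outdir / "novel_candidates.tsv", sep="\t", index=False)
    called = table[table["novel_id"] != ""]
    write_fasta(
        {r.novel_id: r.precursor_seq for r in called.itertuples(index=False)},
        outdir / "novel_precursors.fa",
    )
    with open(outdir / "novel_structures.txt", "w") as fh:
        for r in called.itertuples(index=False):
            fh.write(f">{r.novel_id}\n{r.precursor_seq}\n{r.structure} ({r.mfe:.1f})\n")
    bed = called.rename(
        columns={"window_start": "start", "window_end": "end", "novel_id": "name"}
    )[["chrom", "start", "end", "name", "strand"]].copy()
    bed["score"] = 0
    write_bed(bed[["chrom", "start", "end", "name", "score", "strand"]], outdir / "novel_mirna.bed")


def stage_de(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "de", "known_mirna_counts.tsv", "novel_candidates.tsv")
    totals = _load_totals(outdir)
    known = pd.read_csv(outdir / "known_mirna_counts.tsv", sep="\t")
    known_de, known_summary = de.de_table(
        known, *totals, alpha=cfg.alpha, min_fold=cfg.min_fold, floor_tpm=cfg.floor_tpm
    )
    known_de.to_csv(outdir / "de_known.tsv", sep="\t", index=False)
    render_tables(known_de).to_csv(outdir / "de_known_rendered.tsv", sep="\t", index=False)

    candidates = pd.read_csv(outdir / "novel_candidates.tsv", sep="\t", keep_default_na=False)
    called = candidates[candidates["novel_id"] != ""].rename(
        columns={"novel_id": "mirna_id"}
    )
    if called.empty:
        novel_de = pd.DataFrame(columns=known_de.columns)
        novel_summary = {k: 0 for k in known_summary}
    else:
        novel_de, novel_summary = de.de_table(
            called[["mirna_id", "count_a", "count_b"]],
            *totals,
            alpha=cfg.alpha,
            min_fold=cfg.min_fold,
            floor_tpm=cfg.floor_tpm,
        )
    novel_de.to_csv(outdir / "de_novel.tsv", sep="\t", index=False)
    render_tables(novel_de).to_csv(outdir / "de_novel_rendered.tsv", sep="\t", index=False)
    with open(outdir / "de_summary.json", "w") as fh:
        json.dump({"known": known_summary, "novel": novel_summary}, fh, sort_keys=True, indent=1)


def stage_targets(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "targets", "de_known.tsv", "features.gff3", "genome.fa", "utrs.fa")
    de_known = pd.read_csv(outdir / "de_known.tsv", sep="\t")
    sig = de_known[de_known["call"] != "NS"]
    genome = _load_genome(outdir)
    features = read_gff3(outdir / "features.gff3")
    matures = features[features["type"].isin({"miRNA", "mature_miRNA"})]
    seqs = {}
    for m in matures.itertuples(index=False):
        if m.feature_id in set(sig["mirna_id"]):
            s = genome[m.start : m.end]
            from .io import revcomp as _rc

            seqs[m.feature_id] = s if m.strand == "+" else _rc(s)
    utrs = read_fasta(outdir / "utrs.fa")
    predictions = targets.predict_targets_table(
        seqs, utrs, energy_threshold=cfg.energy_threshold
    )
    predictions.to_csv(outdir / "target_sites.tsv", sep="\t", index=False)
    retained = targets.consensus_filter(predictions, min_support=cfg.min_support)
    retained.to_csv(outdir / "targets.tsv", sep="\t", index=False)


def stage_enrich(cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    _require(outdir, "enrich", "targets.tsv", "gene_terms.tsv", "utrs.fa")
    retained = pd.read_csv(outdir / "targets.tsv", sep="\t")
    gene_terms = pd.read_csv(outdir / "gene_terms.tsv", sep="\t")
    universe = sorted(read_fasta(outdir / "utrs.fa"))
    table = targets.enrich(
        retained["gene_id"] if not retained.empty else [],
        gene_terms,
        universe,
        alpha=cfg.alpha,
    )
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)


STAGES = {
    "simulate": stage_simulate,
    "clean": stage_clean,
    "annotate": stage_annotate,
    "quantify": stage_quantify,
    "novel": stage_novel,
    "de": stage_de,
    "targets": stage_targets,
    "enrich": stage_enrich,
}


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Run every stage in order and write the consolidated report."""
    outdir = ensure_dir(outdir)
    for name, fn in STAGES.items():
        fn(cfg, outdir)
    write_report(outdir)
    return outdir / "report.md"


def render_tables(de_df: pd.DataFrame) -> pd.DataFrame:
    """DE results in the published table style.

    log2 fold change to 2 decimals; adjusted p in scientific notation with
    2 decimals (e.g. ``9.04  Up  1.56E-23``).
    """
    if de_df.empty:
        return pd.DataFrame(columns=["mirna_id", "log2_fc", "direction", "p_adj"])
    sig = de_df[de_df["call"] != "NS"]
    return pd.DataFrame(
        {
            "mirna_id": sig["mirna_id"],
            "log2_fc": [f"{v:.2f}" for v in sig["log2_fc"]],
            "direction": sig["call"],
            "p_adj": [f"{v:.2E}" for v in sig["p_adj"]],
        }
    ).reset_index(drop=True)


def parse_rendered_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not df.empty:
        df["log2_fc"] = df["log2_fc"].astype(float)
        df["p_adj"] = df["p_adj"].astype(float)
    return df


def write_report(outdir) -> None:
    outdir = Path(outdir)
    with open(outdir / "qc_clean.json") as fh:
        qc = json.load(fh)
    with open(outdir / "qc_rrna.json") as fh:
        rrna = json.load(fh)
    with open(outdir / "de_summary.json") as fh:
        de_summary = json.load(fh)
    categories = pd.read_csv(outdir / "category_counts.tsv", sep="\t")
    known = pd.read_csv(outdir / "known_mirna_counts.tsv", sep="\t")
    candidates = pd.read_csv(outdir / "novel_candidates.tsv", sep="\t", keep_default_na=False)
    hist = pd.read_csv(outdir / "length_histogram.tsv", sep="\t")
    enrichment = pd.read_csv(outdir / "enrichment.tsv", sep="\t")
    retained = pd.read_csv(outdir / "targets.tsv", sep="\t")

    detected = {
        lib: int((known[f"count_{lib.lower()}"] > 0).sum()) for lib in ("A", "B")
    }
    shared = int(((known["count_a"] > 0) & (known["count_b"] > 0)).sum())
    n_called = int((candidates["novel_id"] != "").sum())

    report = {
        "clean_reads": {lib: qc[lib]["total_clean_reads"] for lib in "AB"},
        "unique_common_fraction": qc["A"]["unique_common"],
        "total_common_fraction": qc["A"]["total_common"],
        "rrna_qc": rrna,
        "known_mature_detected": detected,
        "known_mature_shared": shared,
        "novel_called": n_called,
        "de": de_summary,
        "n_consensus_targets": int(retained["gene_id"].nunique()) if not retained.empty else 0,
        "n_enriched_terms": int(enrichment["significant"].sum()) if not enrichment.empty else 0,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)

    lines = ["# Small-RNA pipeline report", ""]
    lines.append("## Library cleaning")
    for lib in "AB":
        c = qc[lib]["counters"]
        lines.append(
            f"- library {lib}: {c.get('n_input', 0)} raw reads, "
            f"{qc[lib]['total_clean_reads']} clean reads "
            f"(dimer {c.get('n_adapter_dimer', 0)}, no-adapter {c.get('n_no_adapter', 0)}, "
            f"short {c.get('n_too_short', 0)}, long {c.get('n_too_long', 0)})"
        )
    peak = hist.loc[(hist["reads_a"] + hist["reads_b"]).idxmax(), "length"] if len(hist) else "-"
    lines.append(f"- modal insert length: {peak} nt")
    lines.append(
        f"- unique tags common to both libraries: {qc['A']['unique_common']:.4f}; "
        f"read-weighted: {qc['A']['total_common']:.4f}"
    )
    lines.append("")
    lines.append("## Annotation (unique tags / reads A / reads B)")
    for row in categories.itertuples(index=False):
        lines.append(
            f"- {row.category}: {row.unique_tags} / {row.reads_a} / {row.reads_b}"
        )
    for lib in "AB":
        flag = "PASS" if rrna[lib]["pass"] else "FAIL"
        lines.append(
            f"- rRNA QC {lib}: {rrna[lib]['rrna_fraction']:.3f} ({flag})"
        )
    lines.append("")
    lines.append("## Known and novel miRNAs")
    lines.append(
        f"- mature miRNAs detected: A={detected['A']}, B={detected['B']}, shared={shared}"
    )
    lines.append(f"- novel miRNAs called: {n_called}")
    k, n = de_summary["known"], de_summary["novel"]
    lines.append(
        f"- known DE: {k['n_up']} up, {k['n_down']} down "
        f"({k['n_over_16fold_up']} / {k['n_over_16fold_down']} beyond 16-fold)"
    )
    lines.append(f"- novel DE: {n['n_up']} up, {n['n_down']} down")
    lines.append("")
    lines.append("## Targets and enrichment")
    lines.append(f"- consensus target genes: {report['n_consensus_targets']}")
    lines.append(f"- significantly enriched terms: {report['n_enriched_terms']}")
    lines.append("")
    with open(outdir / "report.md", "w") as fh:
        fh.write("\n".join(lines))
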