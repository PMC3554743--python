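"""Genome mapping, priority-rule category assignment and known-miRNA counts.

Every tag is mapped exactly (full length, both strands) and assigned a
single category under the priority rule

    rRNA-class ncRNA (GenBank > Rfam) > known miRNA > repeat > exon > intron

with sense preferred over antisense for exon/intron, unannotated for mapped
tags overlapping nothing, and unmapped for tags absent from the genome.
The read-weighted rRNA-class fraction below 40% serves as the library QC
mark.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io import revcomp

NCRNA_TYPES = {"rRNA", "tRNA", "snRNA", "snoRNA", "scRNA"}
MIRNA_TYPES = {"miRNA_precursor", "miRNA", "mature_miRNA"}
REPEAT_TYPES = {"repeat", "repeat_region"}

#: category priority, best first
CATEGORIES = [
    "rRNA_etc_GenBank",
    "rRNA_etc_Rfam",
    "known_miRNA",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "unannotated",
    "unmapped",
]
_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str


class GenomeIndex:
    """Exact full-length tag mapping via a k-mer seed index over the genome."""

    def __init__(self, genome: dict[str, str] | str, k: int = 12):
        if isinstance(genome, str):
            genome = {"chr1": genome}
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _exact_hits(self, query: str, strand: str) -> list[GenomeHit]:
        hits = []
        for chrom, pos in self.index.get(query[: self.k], []):
            if self.genome[chrom][pos : pos + len(query)] == query:
                hits.append(GenomeHit(chrom, pos, pos + len(query), strand))
        return hits

    def map_tag(self, tag: str) -> list[GenomeHit]:
        """All exact full-length occurrences on both strands, genome order."""
        tag = tag.upper()
        if "N" in tag or len(tag) < self.k:
            return []
        hits = self._exact_hits(tag, "+") + self._exact_hits(revcomp(tag), "-")
        return sorted(hits, key=lambda h: (h.chrom, h.start, h.strand))


def map_tags(tags: pd.DataFrame, genome, k: int = 12) -> dict[str, list[GenomeHit]]:
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, k)
    return {seq: index.map_tag(seq) for seq in tags["sequence"]}


class FeatureIndex:
    """Interval lookup over the annotation feature table."""

    def __init__(self, features: pd.DataFrame):
        self.features = features
        self.trees: dict[str, IntervalTree] = {}
        for row in features.itertuples(index=False):
            if row.type == "gene":
                continue  # exon/intron children carry the annotation
            tree = self.trees.setdefault(row.chrom, IntervalTree())
            tree.addi(row.start, row.end, row)

    def overlapping(self, chrom: str, start: int, end: int):
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start, end)),
            key=lambda r: (r.start, r.feature_id),
        )


def _feature_category(feature, hit_strand: str) -> str | None:
    ftype = feature.type
    if ftype in NCRNA_TYPES:
        return "rRNA_etc_GenBank" if feature.source == "GenBank" else "rRNA_etc_Rfam"
    if ftype in MIRNA_TYPES:
        # miRNA assignment is strand-specific
        return "known_miRNA" if feature.strand == hit_strand else None
    if ftype in REPEAT_TYPES:
        return "repeat"
    if ftype == "exon":
        return "exon_sense" if feature.strand == hit_strand else "exon_antisense"
    if ftype == "intron":
        return "intron_sense" if feature.strand == hit_strand else "intron_antisense"
    return None


def assign_categories(
    tags: pd.DataFrame,
    hits_by_seq: dict[str, list[GenomeHit]],
    features: FeatureIndex | pd.DataFrame,
) -> pd.DataFrame:
    """One category per tag under the priority rule.

    The best (highest-priority) category over all of a tag's hits wins;
    ties between hits are broken by genome order of the hits.  Returns one
    row per tag with the chosen hit and feature.
    """
    findex = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    rows = []
    for row in tags.itertuples(index=False):
        hits = hits_by_seq.get(row.sequence, [])
        best = (_RANK["unmapped"], -1, None, None)  # rank, hit order, hit, feature
        if hits:
            best = (_RANK["unannotated"], 0, hits[0], None)
            for order, hit in enumerate(hits):
                for feat in findex.overlapping(hit.chrom, hit.start, hit.end):
                    cat = _feature_category(feat, hit.strand)
                    if cat is None:
                        continue
                    key = (_RANK[cat], order, hit, feat)
                    if key[:2] < best[:2]:
                        best = key
        rank, _, hit, feat = best
        rows.append(
            {
                "sequence": row.sequence,
                "count_a": row.count_a,
                "count_b": row.count_b,
                "category": CATEGORIES[rank],
                "feature_id": feat.feature_id if feat is not None else "",
                "chrom": hit.chrom if hit else "",
                "start": hit.start if hit else -1,
                "end": hit.end if hit else -1,
                "strand": hit.strand if hit else ".",
                "n_hits": len(hits),
            }
        )
    return pd.DataFrame(rows)


def category_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Unique-tag and read-weighted counts per category (pie-chart table)."""
    rows = []
    for cat in CATEGORIES:
        sub = annotated[annotated["category"] == cat]
        rows.append(
            {
                "category": cat,
                "unique_tags": len(sub),
                "reads_a": int(sub["count_a"].sum()),
                "reads_b": int(sub["count_b"].sum()),
            }
        )
    return pd.DataFrame(rows)


def chromosome_strand_table(
    annotated: pd.DataFrame, hits_by_seq: dict[str, list[GenomeHit]]
) -> pd.DataFrame:
    """Unique-tag counts per chromosome and strand (mapping-distribution table)."""
    counts: dict[tuple[str, str], int] = {}
    for seq in annotated.loc[annotated["category"] != "unmapped", "sequence"]:
        seen = {(h.chrom, h.strand) for h in hits_by_seq.get(seq, [])}
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"chrom": c, "strand": s, "unique_tags": n}
        for (c, s), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "strand", "unique_tags"])


def quantify_known(
    annotated: pd.DataFrame,
    features: pd.DataFrame,
    totals: tuple[int, int],
    isomir_window: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count tags into mature miRNA and precursor records with TPM.

    A tag counts toward a mature arm when its chosen hit is on the same
    strand, lies fully inside the precursor, and its 5' end is within
    ``isomir_window`` of the annotated mature 5' end; tags inside a
    precursor matching neither arm count toward the precursor only.
    Returns (mature table, precursor table); the mature table contains every
    reference arm, detected or not.
    """
    matures = features[features["type"].isin({"miRNA", "mature_miRNA"})]
    precursors = features[features["type"] == "miRNA_precursor"]
    prec_by_id = {r.feature_id: r for r in precursors.itertuples(index=False)}
    mature_counts = {r.feature_id: [0, 0] for r in matures.itertuples(index=False)}
    prec_counts = {r.feature_id: [0, 0] for r in precursors.itertuples(index=False)}

    known = annotated[annotated["category"] == "known_miRNA"]
    for row in known.itertuples(index=False):
        # locate the precursor the chosen hit falls in
        assigned_prec = None
        feat = row.feature_id
        if feat in prec_counts:
            assigned_prec = feat
        else:
            for m in matures.itertuples(index=False):
                if m.feature_id == feat:
                    assigned_prec = m.parent
                    break
        tag5 = row.start if row.strand == "+" else row.end - 1
        counted = False
        for m in matures.itertuples(index=False):
            if assigned_prec and m.parent != assigned_prec:
                continue
            if m.chrom != row.chrom or m.strand != row.strand:
                continue
            prec = prec_by_id.get(m.parent)
            if prec is not None and not (row.start >= prec.start and row.end <= prec.end):
                continue
            m5 = m.start if m.strand == "+" else m.end - 1
            if abs(tag5 - m5) <= isomir_window:
                mature_counts[m.feature_id][0] += row.count_a
                mature_counts[m.feature_id][1] += row.count_b
                if m.parent in prec_counts:
                    prec_counts[m.parent][0] += row.count_a
                    prec_counts[m.parent][1] += row.count_b
                counted = True
                break
        if not counted and assigned_prec in prec_counts:
            prec_counts[assigned_prec][0] += row.count_a
            prec_counts[assigned_prec][1] += row.count_b

    total_a, total_b = totals
    mature_rows = []
    for m in matures.itertuples(index=False):
        ca, cb = mature_counts[m.feature_id]
        mature_rows.append(
            {
                "mirna_id": m.feature_id,
                "precursor_id": m.parent,
                "count_a": ca,
                "count_b": cb,
                "tpm_a": ca / total_a * 1e6 if total_a else 0.0,
                "tpm_b": cb / total_b * 1e6 if total_b else 0.0,
            }
        )
    prec_rows = [
        {"precursor_id": pid, "count_a": ca, "count_b": cb}
        for pid, (ca, cb) in sorted(prec_counts.items())
    ]
    return pd.DataFrame(mature_rows), pd.DataFrame(prec_rows)


def qc_rrna_fraction(annotated: pd.DataFrame, totals: tuple[int, int]) -> dict:
    """Read-weighted rRNA-class fraction per library; FAIL at >= 40%."""
    mask = annotated["category"].isin(["rRNA_etc_GenBank", "rRNA_etc_Rfam"])
    out = {}
    for lib, col, total in (("A", "count_a", totals[0]), ("B", "count_b", totals[1])):
        frac = annotated.loc[mask, col].sum() / total if total else 0.0
        out[lib] = {"rrna_fraction": float(frac), "pass": bool(frac < 0.40)}
    return out
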