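"""Mapping, priority-rule annotation, known-miRNA quantification and QC."""

import numpy as np
import pandas as pd
import pytest

from mirseqkit.annotate import (
    CATEGORIES,
    NCRNA_TYPES,
    GenomeIndex,
    assign_categories,
    category_summary,
    chromosome_strand_table,
    map_tags,
    qc_rrna_fraction,
    quantify_known,
)
from mirseqkit.io import read_fasta, read_gff3, revcomp

from helpers import brute_force_category


def _feature(chrom, source, ftype, start, end, strand, fid, parent=""):
    return {
        "chrom": chrom, "source": source, "type": ftype, "start": start,
        "end": end, "strand": strand, "feature_id": fid, "parent": parent,
    }


def _tags(seqs):
    return pd.DataFrame(
        {"sequence": seqs, "count_a": [1] * len(seqs), "count_b": [0] * len(seqs)}
    )


@pytest.fixture()
def toy():
    rng = np.random.default_rng(17)
    genome = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=2_000)])
    features = pd.DataFrame(
        [
            _feature("chr1", "GenBank", "rRNA", 100, 220, "+", "rrna-1"),
            _feature("chr1", "Rfam", "tRNA", 180, 230, "+", "trna-1"),
            _feature("chr1", "miRBaseLike", "miRNA_precursor", 200, 256, "+", "mirX"),
            _feature("chr1", "miRBaseLike", "miRNA", 200, 222, "+", "mirX-5p", "mirX"),
            _feature("chr1", "miRBaseLike", "miRNA", 234, 256, "+", "mirX-3p", "mirX"),
            _feature("chr1", "RepeatLib", "repeat", 400, 500, "+", "rep-1"),
            _feature("chr1", "GeneModel", "gene", 600, 900, "-", "gene-1"),
            _feature("chr1", "GeneModel", "exon", 600, 700, "-", "g1.e1", "gene-1"),
            _feature("chr1", "GeneModel", "intron", 700, 800, "+", "g1.i1", "gene-1"),
        ]
    )
    return genome, features


def test_map_tags_exact_both_strands(toy):
    genome, _ = toy
    tag = genome[100:122]
    hits = GenomeIndex(genome).map_tag(tag)
    assert any(h.start == 100 and h.strand == "+" for h in hits)
    rc_hits = GenomeIndex(genome).map_tag(revcomp(tag))
    assert any(h.start == 100 and h.strand == "-" for h in rc_hits)
    assert GenomeIndex(genome).map_tag("N" * 22) == []
    assert GenomeIndex(genome).map_tag("ACGT") == []  # below seed size


def test_map_tags_palindrome_hits_both_strands():
    half = "ACCGTTAGCAT"
    pal = half + revcomp(half)
    genome = "T" * 40 + pal + "G" * 40
    hits = GenomeIndex(genome).map_tag(pal)
    assert {h.strand for h in hits} == {"+", "-"}
    assert all(h.start == 40 for h in hits)


def test_priority_rule_examples(toy):
    genome, features = toy
    seqs = [
        genome[150:172],  # rRNA (GenBank) only
        genome[222:244],  # Rfam tRNA + 3p arm: ncRNA outranks miRNA
        genome[240:262],  # inside precursor/3p arm only
        genome[420:442],  # repeat
        genome[610:632],  # exon on minus strand, plus-strand hit
        genome[690:712],  # exon_antisense outranks intron_sense
        genome[1500:1522],  # mapped, feature-free region
    ]
    annotated = assign_categories(_tags(seqs), map_tags(_tags(seqs), genome), features)
    got = dict(zip(annotated["sequence"], annotated["category"]))
    assert got[genome[150:172]] == "rRNA_etc_GenBank"
    assert got[genome[222:244]] == "rRNA_etc_Rfam"
    assert got[genome[240:262]] == "known_miRNA"
    assert got[genome[420:442]] == "repeat"
    assert got[genome[610:632]] == "exon_antisense"
    assert got[genome[690:712]] == "exon_antisense"
    assert got[genome[1500:1522]] == "unannotated"
    unmapped = assign_categories(
        _tags(["ACGTACGTACGTACGTACGTAA"]),
        {"ACGTACGTACGTACGTACGTAA": []},
        features,
    )
    assert unmapped.loc[0, "category"] == "unmapped"


def test_antisense_hit_is_not_a_known_mirna(toy):
    genome, features = toy
    tag = revcomp(genome[234:256])  # 3p arm, minus strand
    annotated = assign_categories(_tags([tag]), map_tags(_tags([tag]), genome), features)
    assert annotated.loc[0, "category"] != "known_miRNA"


def test_assignment_matches_brute_force_oracle(run_dir):
    annotated = pd.read_csv(run_dir / "annotation.tsv", sep="\t", keep_default_na=False)
    genome = read_fasta(run_dir / "genome.fa")
    features = read_gff3(run_dir / "features.gff3")
    sample = annotated.sample(n=min(300, len(annotated)), random_state=0)
    hits = map_tags(sample, genome)
    for row in sample.itertuples(index=False):
        expected = brute_force_category(
            hits[row.sequence], features, CATEGORIES, NCRNA_TYPES
        )
        assert row.category == expected, row.sequence


def test_category_summary_is_a_partition(run_dir):
    annotated = pd.read_csv(run_dir / "annotation.tsv", sep="\t", keep_default_na=False)
    summary = category_summary(annotated)
    assert summary["unique_tags"].sum() == len(annotated)
    assert summary["reads_a"].sum() == annotated["count_a"].sum()
    assert set(summary["category"]) == set(CATEGORIES)


def test_chromosome_strand_table_counts(toy):
    genome, features = toy
    seqs = [genome[150:172], revcomp(genome[420:442])]
    tags = _tags(seqs)
    hits = map_tags(tags, genome)
    annotated = assign_categories(tags, hits, features)
    table = chromosome_strand_table(annotated, hits)
    counts = {(r.chrom, r.strand): r.unique_tags for r in table.itertuples(index=False)}
    assert counts[("chr1", "+")] >= 1 and counts[("chr1", "-")] >= 1


def test_quantify_known_isomir_window(toy):
    genome, features = toy

    def row(start, end, fid, ca, cb):
        return {
            "sequence": genome[start:end], "count_a": ca, "count_b": cb,
            "category": "known_miRNA", "feature_id": fid, "chrom": "chr1",
            "start": start, "end": end, "strand": "+", "n_hits": 1,
        }

    annotated = pd.DataFrame(
        [
            row(200, 222, "mirX-5p", 40, 10),  # exact mature arm
            row(202, 224, "mirX-5p", 5, 5),  # 5' shift of 2: isomiR, counted
            row(205, 227, "mirX", 3, 0),  # shift of 5: precursor only
        ]
    )
    mature, precursor = quantify_known(annotated, features, (1_000_000, 1_000_000))
    m = mature.set_index("mirna_id")
    assert m.loc["mirX-5p", ["count_a", "count_b"]].tolist() == [45, 15]
    assert m.loc["mirX-5p", "tpm_a"] == pytest.approx(45.0)
    assert m.loc["mirX-3p", "count_a"] == 0  # undetected arm still reported
    p = precursor.set_index("precursor_id")
    assert p.loc["mirX", "count_a"] == 48  # arm reads + inside-precursor reads


def test_quantification_recovers_planted_counts(sim, run_dir):
    from collections import Counter

    s, _, _ = sim
    mature = pd.read_csv(run_dir / "known_mirna_counts.tsv", sep="\t")
    ca = Counter(s.truth.provenance["A"])
    cb = Counter(s.truth.provenance["B"])
    got = mature.set_index("mirna_id")
    for fid in s.truth.mirnas:
        for arm in ("5p", "3p"):
            assert got.loc[f"{fid}-{arm}", "count_a"] == ca[f"mirna:{fid}-{arm}"]
            assert got.loc[f"{fid}-{arm}", "count_b"] == cb[f"mirna:{fid}-{arm}"]


def test_rrna_qc_boundary():
    annotated = pd.DataFrame(
        {
            "sequence": ["A" * 20, "C" * 20],
            "count_a": [390, 610],
            "count_b": [400, 600],
            "category": ["rRNA_etc_GenBank", "unannotated"],
        }
    )
    qc = qc_rrna_fraction(annotated, (1_000, 1_000))
    assert qc["A"]["rrna_fraction"] == pytest.approx(0.39) and qc["A"]["pass"]
    assert qc["B"]["rrna_fraction"] == pytest.approx(0.40) and not qc["B"]["pass"]
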