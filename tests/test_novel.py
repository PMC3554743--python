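"""Clustering, precursor extraction, Dicer gate and novel-miRNA calls."""

import numpy as np
import pandas as pd
import pytest

from mirseqkit.annotate import GenomeHit
from mirseqkit.io import revcomp
from mirseqkit.novel import (
    Cluster,
    ClusterMember,
    call_novel,
    cluster_unannotated,
    dicer_consistency,
    extract_precursor,
)

from helpers import brute_force_merge


def _annotated(rows):
    return pd.DataFrame(
        rows, columns=["sequence", "count_a", "count_b", "category"]
    )


def _hits(mapping):
    return {
        seq: [GenomeHit("chr1", s, e, strand) for s, e, strand in hits]
        for seq, hits in mapping.items()
    }


def test_cluster_merges_within_gap_same_strand_only():
    annotated = _annotated(
        [
            ("t1", 3, 1, "unannotated"),
            ("t2", 2, 2, "unannotated"),
            ("t3", 1, 1, "unannotated"),
            ("t4", 1, 0, "unannotated"),
            ("t5", 9, 9, "known_miRNA"),  # not clustered
        ]
    )
    hits = _hits(
        {
            "t1": [(100, 122, "+")],
            "t2": [(130, 152, "+")],  # gap 8 <= 10: merged
            "t3": [(200, 222, "+")],  # gap 48: new cluster
            "t4": [(100, 122, "-")],  # same span, other strand
            "t5": [(100, 122, "+")],
        }
    )
    clusters = cluster_unannotated(annotated, hits, merge_distance=10)
    spans = sorted((c.strand, c.start, c.end, len(c.members)) for c in clusters)
    assert spans == [("+", 100, 152, 2), ("+", 200, 222, 1), ("-", 100, 122, 1)]
    merged = next(c for c in clusters if c.end == 152)
    assert merged.count_a == 5 and merged.count_b == 3


def test_cluster_spans_match_brute_force_merge():
    rng = np.random.default_rng(9)
    starts = sorted(int(x) for x in rng.integers(0, 5_000, size=120))
    rows, hits = [], {}
    intervals = []
    for i, s in enumerate(starts):
        e = s + int(rng.integers(18, 31))
        rows.append((f"t{i}", 1, 1, "unannotated"))
        hits[f"t{i}"] = [(s, e, "+")]
        intervals.append((s, e))
    clusters = cluster_unannotated(_annotated(rows), _hits(hits), merge_distance=10)
    got = sorted((c.start, c.end) for c in clusters)
    assert got == brute_force_merge(intervals, gap=10)
    assert sum(len(c.members) for c in clusters) == len(intervals)


def test_dicer_consistency_fractions():
    def member(start, ca):
        return ClusterMember("x", start, start + 22, ca, 0)

    uniform = Cluster("chr1", "+", 0, 22, [member(100, 5), member(100, 5)])
    assert dicer_consistency(uniform) == (1.0, True)
    split = Cluster("chr1", "+", 0, 22, [member(100, 5), member(103, 5)])
    frac, ok = dicer_consistency(split)
    assert frac == 0.5 and not ok
    skewed = Cluster("chr1", "+", 0, 22, [member(100, 8), member(103, 2)])
    frac, ok = dicer_consistency(skewed)
    assert frac == pytest.approx(0.8) and ok
    # minus strand: the 5' end is the rightmost base
    minus = Cluster(
        "chr1", "-", 0, 22,
        [ClusterMember("x", 100, 122, 5, 0), ClusterMember("y", 98, 122, 5, 0)],
    )
    assert dicer_consistency(minus) == (1.0, True)


def test_extract_precursor_windows_and_clipping():
    genome = "ACGT" * 30  # 120 nt
    cluster = Cluster("chr1", "+", 30, 52, [])
    w5, w3 = extract_precursor(cluster, genome, flank_up=70, flank_down=70)
    assert (w5.genomic_start, w5.genomic_end) == (30, 120)  # clipped right
    assert w5.sequence == genome[30:120]
    assert (w5.arm_start, w5.arm_end) == (0, 22)
    assert (w3.genomic_start, w3.genomic_end) == (0, 52)  # clipped left
    assert w3.sequence[w3.arm_start : w3.arm_end] == genome[30:52]
    minus = Cluster("chr1", "-", 30, 52, [])
    m5, m3 = extract_precursor(minus, genome, flank_up=20, flank_down=20)
    assert m5.sequence == revcomp(genome[10:52])
    assert m5.sequence[m5.arm_start : m5.arm_end] == revcomp(genome[30:52])


def test_expression_gate_is_inclusive_and_switchable():
    genome = "A" * 200  # folds open: only the expression flag is under test
    def cluster(ca, cb):
        return Cluster(
            "chr1", "+", 50, 72, [ClusterMember("A" * 22, 50, 72, ca, cb)]
        )

    table = call_novel([cluster(1, 1)], genome, (1_000_000, 1_000_000), min_reads=1)
    assert table.loc[0, "tpm_a"] == 1.0  # exactly at the threshold
    assert bool(table.loc[0, "expression_pass"])
    table = call_novel([cluster(1, 0)], genome, (1_000_000, 1_000_000), min_reads=1)
    assert not bool(table.loc[0, "expression_pass"])
    table = call_novel(
        [cluster(1, 0)], genome, (1_000_000, 1_000_000),
        min_reads=1, require_both_samples=False,
    )
    assert bool(table.loc[0, "expression_pass"])


def test_min_read_support_filters_clusters():
    genome = "A" * 200
    c = Cluster("chr1", "+", 50, 72, [ClusterMember("A" * 22, 50, 72, 1, 1)])
    assert call_novel([c], genome, (1_000, 1_000), min_reads=3).empty


def test_mfe_gate_is_strict(run_dir):
    table = pd.read_csv(run_dir / "novel_candidates.tsv", sep="\t", keep_default_na=False)
    assert len(table) > 0
    assert (table["mfe_pass"] == (table["mfe"] < -20.0)).all()


def test_verdict_is_conjunction_of_gates(run_dir):
    table = pd.read_csv(run_dir / "novel_candidates.tsv", sep="\t", keep_default_na=False)
    expected = (
        table["hairpin_shape"]
        & table["mfe_pass"]
        & table["dicer_pass"]
        & table["expression_pass"]
    )
    assert (table["verdict"] == expected).all()
    assert (table["called"] == (table["novel_id"] != "")).all()
    # an id is only ever assigned to an accepted candidate
    assert table.loc[table["called"], "verdict"].all()
    ids = table.loc[table["called"], "novel_id"]
    assert ids.is_unique


def test_hidden_hairpins_are_recovered(run_dir):
    truth = pd.read_csv(run_dir / "ground_truth.tsv", sep="\t")
    hidden = truth[truth["hidden"]]
    table = pd.read_csv(run_dir / "novel_candidates.tsv", sep="\t", keep_default_na=False)
    called = table[table["called"]]
    for hp in hidden.itertuples(index=False):
        overlap = called[
            (called["window_start"] < hp.end) & (hp.start < called["window_end"])
        ]
        assert len(overlap) >= 1, hp.hairpin_id
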