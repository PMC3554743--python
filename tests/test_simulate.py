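"""Generator: determinism, planted structure, composition and null behavior."""

import numpy as np
import pytest
from scipy import stats

from mirseqkit.fold import fold_rna
from mirseqkit.io import revcomp
from mirseqkit.reads import trim_adapter
from mirseqkit.simulate import (
    SimConfig,
    build_genome,
    config_from_dict,
    config_to_dict,
    simulate_libraries,
    simulate_two_library_counts,
)


def tiny_config(**kw):
    base = dict(
        genome_length=9_000,
        n_known_mirnas=3,
        n_hidden_hairpins=1,
        n_other_ncrna=4,
        n_repeats=2,
        n_genes=2,
        library_sizes=(800, 800),
        n_utr_genes=20,
        seed=11,
    )
    base.update(kw)
    return SimConfig(**base)


def test_generator_is_deterministic():
    s1, s2 = build_genome(tiny_config()), build_genome(tiny_config())
    assert s1.sequence == s2.sequence
    assert s1.features.equals(s2.features)
    a1, b1 = simulate_libraries(s1)
    a2, b2 = simulate_libraries(s2)
    assert a1 == a2 and b1 == b2


def test_library_sizes_are_exact():
    s = build_genome(tiny_config())
    a, b = simulate_libraries(s)
    assert len(a) == 800 and len(b) == 800
    assert all(len(seq) == 50 for _, seq, _ in a)


def test_empty_libraries_are_valid():
    s = build_genome(tiny_config(library_sizes=(0, 0)))
    a, b = simulate_libraries(s)
    assert a == [] and b == []


def test_annotation_contains_known_but_not_hidden_hairpins():
    s = build_genome(tiny_config())
    prec = s.features[s.features["type"] == "miRNA_precursor"]
    mature = s.features[s.features["type"] == "miRNA"]
    assert len(prec) == 3 and len(mature) == 6
    assert not any("hidden" in fid for fid in s.features["feature_id"])
    assert set(s.truth.hidden) == {"hidden-1"}


def test_no_mirna_study_is_buildable():
    s = build_genome(tiny_config(n_known_mirnas=0, n_hidden_hairpins=0))
    assert (s.features["type"] == "miRNA_precursor").sum() == 0


def test_planted_hairpins_are_genuine_stemloops():
    s = build_genome(tiny_config())
    for hp in s.truth.all_hairpins():
        assert hp.seq_3p == revcomp(hp.seq_5p)
        precursor = s.sequence[hp.start : hp.end]
        assert precursor.startswith(hp.seq_5p) and precursor.endswith(hp.seq_3p)
        assert fold_rna(precursor).mfe < -20.0


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(insert_length_dist={22: 0.5}).validate()
    with pytest.raises(ValueError):
        SimConfig(insert_length_dist={17: 1.0}).validate()
    with pytest.raises(ValueError):
        SimConfig(library_sizes=(-1, 10)).validate()
    with pytest.raises(ValueError):
        SimConfig(first_base_u_prob=1.5).validate()


def test_config_dict_round_trip():
    cfg = tiny_config(log2_fc_table={"mir-1": 2.0})
    assert config_from_dict(config_to_dict(cfg)) == cfg


def test_noise_inserts_are_genome_absent(sim):
    s, lib_a, _ = sim
    rc = revcomp(s.sequence)
    noise = [
        seq
        for (_, seq, _), label in zip(lib_a, s.truth.provenance["A"])
        if label == "noise"
    ][:50]
    assert noise, "expected some noise reads"
    for read in noise:
        insert = trim_adapter(read).insert
        assert insert is not None
        assert insert not in s.sequence and insert not in rc


def test_first_base_u_bias_on_designed_arms():
    cfg = tiny_config(genome_length=120_000, n_known_mirnas=40, first_base_u_prob=0.8)
    s = build_genome(cfg)
    frac = np.mean([hp.seq_5p.startswith("T") for hp in s.truth.mirnas.values()])
    assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / 40)


def test_null_fold_changes_center_on_unity():
    # pooled chi-square goodness of fit on per-arm A-vs-B counts over seeds
    stat, dof = 0.0, 0
    for seed in range(20):
        s = build_genome(tiny_config(library_sizes=(4_000, 4_000), seed=100 + seed))
        simulate_libraries(s)
        from collections import Counter

        ca = Counter(s.truth.provenance["A"])
        cb = Counter(s.truth.provenance["B"])
        for label in set(ca) | set(cb):
            if not label.startswith(("mirna:", "hidden:")):
                continue
            x, y = ca.get(label, 0), cb.get(label, 0)
            if x + y == 0:
                continue
            stat += (x - y) ** 2 / (x + y)
            dof += 1
    p = stats.chi2.sf(stat, dof)
    assert p > 0.01


def test_planted_fold_change_recovered_from_reads():
    from collections import Counter

    for seed in range(12):
        cfg = tiny_config(
            n_known_mirnas=1,
            n_hidden_hairpins=0,
            library_sizes=(6_000, 6_000),
            mirna_tpm_range=(30_000.0, 30_000.0),
            log2_fc_table={"mir-1": 3.0},
            seed=200 + seed,
        )
        s = build_genome(cfg)
        simulate_libraries(s)
        ca = Counter(s.truth.provenance["A"])["mirna:mir-1-5p"]
        cb = Counter(s.truth.provenance["B"])["mirna:mir-1-5p"]
        assert ca > 0 and cb > 0
        assert abs(np.log2(cb / ca) - 3.0) <= 0.5


def test_count_level_simulator_contract():
    rng = np.random.default_rng(1)
    tpm = np.full(10, 2_000.0)
    fc = np.zeros(10)
    a, b = simulate_two_library_counts(tpm, fc, (50_000, 50_000), rng)
    assert a.sum() <= 50_000 and b.sum() <= 50_000
    assert a.shape == (10,)
    with pytest.raises(ValueError):
        simulate_two_library_counts(np.array([2e6]), np.array([0.0]), (100, 100), rng)


def test_written_study_round_trips(tmp_path, sim):
    s, _, _ = sim
    s.write(tmp_path)
    from mirseqkit.io import read_fasta, read_gff3

    genome = read_fasta(tmp_path / "genome.fa")
    assert genome[s.chrom] == s.sequence
    feats = read_gff3(tmp_path / "features.gff3")
    assert len(feats) == len(s.features)
    utrs = read_fasta(tmp_path / "utrs.fa")
    assert utrs == s.utrs
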