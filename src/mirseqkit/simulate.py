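"""Synthetic small-RNA-seq study generator.

Builds a miniature genome carrying designed miRNA stem-loops, housekeeping
ncRNA loci, repeats and protein-coding gene models, plus a set of *hidden*
hairpins that are written into the genome but omitted from the annotation —
the truth set for novel-miRNA discovery.  Two adapter-ligated 50-nt FASTQ
libraries are then drawn with known per-miRNA abundances and configurable
log2 fold changes between libraries, so every downstream stage (cleaning,
annotation, quantification, hairpin calling, differential expression) can be
verified against ground truth.

Library composition: mature-arm reads follow ``library_size x TPM / 1e6``
(library B additionally scaled by ``2**log2FC``); the residual read mass is
split between ncRNA fragments (which map to annotated loci) and unmappable
noise inserts, and the per-read source counts are drawn multinomially so the
emitted total equals the configured library size exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import revcomp, write_fasta, write_fastq, write_gff3, ensure_dir

#: DNA form of the 3' sequencing adaptor ligated to the small-RNA insert.
ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTGT"

READ_LENGTH = 50

_BASES = np.array(list("ACGT"))

#: default insert-length distribution, peaked at the canonical 22 nt
DEFAULT_LENGTH_DIST = {
    18: 0.02, 19: 0.03, 20: 0.06, 21: 0.12, 22: 0.45, 23: 0.12,
    24: 0.07, 25: 0.05, 26: 0.03, 27: 0.02, 28: 0.01, 29: 0.01, 30: 0.01,
}

_NCRNA_TYPES = [("rRNA", 120), ("tRNA", 76), ("snRNA", 110), ("snoRNA", 90), ("scRNA", 100)]

ARM_LENGTH = 22
LOOP_LENGTH = 12  # > default cluster merge distance, so arms cluster separately


class PlacementError(RuntimeError):
    """Raised when the configured features cannot fit in the genome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-library experiment."""

    genome_length: int = 60_000
    n_known_mirnas: int = 12
    n_hidden_hairpins: int = 5
    n_other_ncrna: int = 10
    n_repeats: int = 4
    n_genes: int = 4
    library_sizes: tuple[int, int] = (30_000, 30_000)
    log2_fc_table: dict[str, float] = field(default_factory=dict)
    insert_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    first_base_u_prob: float = 0.8
    #: per-arm true abundance in library A, drawn log-uniformly (TPM);
    #: miRNA reads dominate the library, as in a size-selected small-RNA prep
    mirna_tpm_range: tuple[float, float] = (5000.0, 50000.0)
    #: total true-arm TPM is rescaled to at most this per library
    max_total_mirna_tpm: float = 700_000.0
    #: residual (non-miRNA) read mass split:
    #: ncRNA fragments : repeat/exon/intron fragments : unmappable noise
    ncrna_weight: float = 0.10
    genic_weight: float = 0.03
    noise_weight: float = 0.12
    error_rate: float = 0.0
    adapter: str = ADAPTER_3P
    read_length: int = READ_LENGTH
    # synthetic 3'UTR / term annotation for the target-prediction stages
    n_utr_genes: int = 120
    utr_length: int = 400
    n_terms: int = 15
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.insert_length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"insert_length_dist sums to {total}, expected 1")
        if any(not 18 <= k <= 30 for k in self.insert_length_dist):
            raise ValueError("insert lengths must lie in [18, 30]")
        if any(n < 0 for n in self.library_sizes):
            raise ValueError("library_sizes must be non-negative")
        if self.first_base_u_prob < 0 or self.first_base_u_prob > 1:
            raise ValueError("first_base_u_prob must be in [0, 1]")


@dataclass
class HairpinTruth:
    """A planted stem-loop: locus, arms and per-library true arm TPMs."""

    hairpin_id: str
    start: int
    end: int
    mature_5p: tuple[int, int]
    mature_3p: tuple[int, int]
    seq_5p: str
    seq_3p: str
    tpm_5p: tuple[float, float]  # (library A, library B)
    tpm_3p: tuple[float, float]
    hidden: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    mirnas: dict[str, HairpinTruth]
    hidden: dict[str, HairpinTruth]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def all_hairpins(self):
        yield from self.mirnas.values()
        yield from self.hidden.values()


@dataclass
class SimulatedGenome:
    chrom: str
    sequence: str
    features: pd.DataFrame  # hidden hairpins excluded
    truth: GroundTruth
    utrs: dict[str, str]
    gene_terms: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        outdir = ensure_dir(outdir)
        write_fasta({self.chrom: self.sequence}, outdir / "genome.fa")
        write_gff3(self.features, outdir / "features.gff3")
        write_fasta(self.utrs, outdir / "utrs.fa")
        self.gene_terms.to_csv(outdir / "gene_terms.tsv", sep="\t", index=False)
        rows = []
        for hp in self.truth.all_hairpins():
            rows.append(
                {
                    "hairpin_id": hp.hairpin_id,
                    "start": hp.start,
                    "end": hp.end,
                    "hidden": hp.hidden,
                    "seq_5p": hp.seq_5p,
                    "seq_3p": hp.seq_3p,
                    "tpm_5p_a": hp.tpm_5p[0],
                    "tpm_5p_b": hp.tpm_5p[1],
                    "tpm_3p_a": hp.tpm_3p[0],
                    "tpm_3p_b": hp.tpm_3p[1],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _design_arm(rng: np.random.Generator, u_prob: float) -> str:
    """A 22-nt mature arm, GC-rich enough for a stable designed stem."""
    arm = _random_seq(rng, ARM_LENGTH, gc=0.55)
    if rng.random() < u_prob:
        arm = "T" + arm[1:]
    return arm


class _Placer:
    """Non-overlapping interval placement with a spacing buffer."""

    def __init__(self, rng, genome_length, buffer=20):
        self.rng = rng
        self.length = genome_length
        self.buffer = buffer
        self.placed: list[tuple[int, int]] = []

    def place(self, size: int, what: str) -> int:
        for _ in range(2000):
            start = int(self.rng.integers(0, max(1, self.length - size)))
            lo, hi = start - self.buffer, start + size + self.buffer
            if all(e <= lo or s >= hi for s, e in self.placed):
                self.placed.append((start, start + size))
                return start
        raise PlacementError(
            f"cannot place {what} ({size} nt) without overlap in a "
            f"{self.length} nt genome; reduce feature counts or enlarge it"
        )


def build_genome(config: SimConfig) -> SimulatedGenome:
    """Build the genome, its annotation and the ground truth (deterministic)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome = list(_random_seq(rng, config.genome_length))
    placer = _Placer(rng, config.genome_length)
    features: list[dict] = []

    def add_feature(source, ftype, start, end, strand, fid, parent=""):
        features.append(
            {
                "chrom": chrom,
                "source": source,
                "type": ftype,
                "start": start,
                "end": end,
                "strand": strand,
                "feature_id": fid,
                "parent": parent,
            }
        )

    def plant_hairpin(fid: str, hidden: bool) -> HairpinTruth:
        arm5 = _design_arm(rng, config.first_base_u_prob)
        loop = _random_seq(rng, LOOP_LENGTH)
        precursor = arm5 + loop + revcomp(arm5)
        start = placer.place(len(precursor), fid)
        genome[start : start + len(precursor)] = precursor
        m5 = (start, start + ARM_LENGTH)
        m3 = (start + ARM_LENGTH + LOOP_LENGTH, start + len(precursor))
        lo, hi = config.mirna_tpm_range
        tpm5 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        share = rng.uniform(0.15, 0.5)  # 3p arm expressed below 5p
        tpm3 = tpm5 * share
        fc = 2.0 ** config.log2_fc_table.get(fid, 0.0)
        truth = HairpinTruth(
            hairpin_id=fid,
            start=start,
            end=start + len(precursor),
            mature_5p=m5,
            mature_3p=m3,
            seq_5p=arm5,
            seq_3p=revcomp(arm5),
            tpm_5p=(tpm5, tpm5 * fc),
            tpm_3p=(tpm3, tpm3 * fc),
            hidden=hidden,
        )
        if not hidden:
            add_feature("miRBaseLike", "miRNA_precursor", start, start + len(precursor), "+", fid)
            add_feature("miRBaseLike", "miRNA", m5[0], m5[1], "+", f"{fid}-5p", fid)
            add_feature("miRBaseLike", "miRNA", m3[0], m3[1], "+", f"{fid}-3p", fid)
        return truth

    mirnas = {}
    for i in range(config.n_known_mirnas):
        fid = f"mir-{i + 1}"
        mirnas[fid] = plant_hairpin(fid, hidden=False)
    hidden = {}
    for i in range(config.n_hidden_hairpins):
        fid = f"hidden-{i + 1}"
        hidden[fid] = plant_hairpin(fid, hidden=True)

    for i in range(config.n_other_ncrna):
        ftype, size = _NCRNA_TYPES[i % len(_NCRNA_TYPES)]
        source = "GenBank" if i % 2 == 0 else "Rfam"
        start = placer.place(size, ftype)
        add_feature(source, ftype, start, start + size, "+", f"{ftype}-{i + 1}")

    for i in range(config.n_repeats):
        start = placer.place(200, "repeat")
        add_feature("RepeatLib", "repeat", start, start + 200, "+", f"rep-{i + 1}")

    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        start = placer.place(600, "gene")
        gid = f"gene-{i + 1}"
        add_feature("GeneModel", "gene", start, start + 600, strand, gid)
        add_feature("GeneModel", "exon", start, start + 150, strand, f"{gid}.e1", gid)
        add_feature("GeneModel", "intron", start + 150, start + 450, strand, f"{gid}.i1", gid)
        add_feature("GeneModel", "exon", start + 450, start + 600, strand, f"{gid}.e2", gid)

    feature_df = pd.DataFrame(features)
    truth = GroundTruth(mirnas=mirnas, hidden=hidden)
    _rescale_tpms(truth, config.max_total_mirna_tpm)

    utrs, gene_terms = _build_utrs_and_terms(rng, config, mirnas)
    return SimulatedGenome(
        chrom=chrom,
        sequence="".join(genome),
        features=feature_df,
        truth=truth,
        utrs=utrs,
        gene_terms=gene_terms,
        config=config,
    )


def _rescale_tpms(truth: GroundTruth, cap: float) -> None:
    """Keep total true arm TPM within the cap per library (composition)."""
    totals = [0.0, 0.0]
    for hp in truth.all_hairpins():
        for lib in (0, 1):
            totals[lib] += hp.tpm_5p[lib] + hp.tpm_3p[lib]
    worst = max(totals)
    if worst <= cap:
        return
    f = cap / worst
    for hp in truth.all_hairpins():
        hp.tpm_5p = (hp.tpm_5p[0] * f, hp.tpm_5p[1] * f)
        hp.tpm_3p = (hp.tpm_3p[0] * f, hp.tpm_3p[1] * f)


def _build_utrs_and_terms(rng, config, mirnas):
    """Synthetic 3'UTRs with planted 8mer seed sites, plus gene->term map.

    Each known miRNA 5p arm receives a block of target genes carrying an
    exact 8mer site; one term per miRNA is preferentially assigned to its
    targets so downstream enrichment has true signal to find.
    """
    utrs: dict[str, str] = {}
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_utr_genes)]
    for gid in gene_ids:
        utrs[gid] = _random_seq(rng, config.utr_length)
    targets_of: dict[str, list[str]] = {}
    n_targets = max(6, config.n_utr_genes // (4 * max(1, config.n_known_mirnas)))
    for idx, (fid, hp) in enumerate(mirnas.items()):
        arm = hp.seq_5p
        site = revcomp(arm[1:8]) + "A"  # 8mer: 7mer-m8 match + A opposite pos 1
        chosen = [gene_ids[(idx * n_targets + k) % len(gene_ids)] for k in range(n_targets)]
        targets_of[fid] = chosen
        for gid in chosen:
            pos = int(rng.integers(10, config.utr_length - 20))
            s = utrs[gid]
            utrs[gid] = s[:pos] + site + s[pos + len(site):]
    # background terms are drawn from the first block; one reserved term per
    # miRNA is assigned to its planted targets so enrichment has true signal
    n_background = max(1, config.n_terms // 2)
    terms = [f"TERM:{i + 1:03d}" for i in range(config.n_terms)]
    rows = []
    for gid in gene_ids:
        k = 1 + int(rng.integers(0, 3))
        for t in rng.choice(n_background, size=min(k, n_background), replace=False):
            rows.append({"gene": gid, "term": terms[int(t)]})
    n_planted = config.n_terms - n_background
    for idx, (fid, chosen) in enumerate(targets_of.items()):
        term = terms[n_background + idx % n_planted] if n_planted else terms[0]
        for gid in chosen:
            rows.append({"gene": gid, "term": term})
    gene_terms = pd.DataFrame(rows).drop_duplicates().sort_values(
        ["gene", "term"], ignore_index=True
    )
    return utrs, gene_terms


def _make_read(insert: str, adapter: str, read_length: int) -> str:
    tail = (adapter * ((read_length // len(adapter)) + 2))
    return (insert + tail)[:read_length]


def simulate_libraries(
    sim: SimulatedGenome, outdir=None
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Draw the two FASTQ libraries; returns the read records per library.

    Records are ``(read_id, sequence, quality)``; per-read provenance labels
    are stored in ``sim.truth.provenance``.  When ``outdir`` is given the
    libraries are also written as ``lib_A.fastq`` / ``lib_B.fastq``.
    """
    config = sim.config
    rng = np.random.default_rng(config.seed + 1)
    genome = sim.sequence
    genome_rc = revcomp(genome)
    lengths = sorted(config.insert_length_dist)
    length_p = np.array([config.insert_length_dist[k] for k in lengths])

    # arm components with expected counts per library
    arms = []  # (label, insert, expected_A, expected_B)
    for hp in sim.truth.all_hairpins():
        kind = "hidden" if hp.hidden else "mirna"
        for arm_name, seq, tpm in (
            ("5p", hp.seq_5p, hp.tpm_5p),
            ("3p", hp.seq_3p, hp.tpm_3p),
        ):
            arms.append((f"{kind}:{hp.hairpin_id}-{arm_name}", seq, tpm[0], tpm[1]))

    ncrna_feats = sim.features[
        sim.features["type"].isin([t for t, _ in _NCRNA_TYPES])
    ].reset_index(drop=True)
    genic_feats = sim.features[
        sim.features["type"].isin(["repeat", "exon", "intron"])
    ].reset_index(drop=True)

    def draw_fragment(feats, label_prefix, sense_fraction=0.9):
        row = feats.iloc[int(rng.integers(0, len(feats)))]
        ln = int(rng.choice(lengths, p=length_p))
        ln = min(ln, row.end - row.start)
        start = int(rng.integers(row.start, row.end - ln + 1))
        frag = genome[start : start + ln]
        # fragments are mostly sense relative to the source transcript
        sense = rng.random() < sense_fraction
        if (row.strand == "-") == sense:
            frag = revcomp(frag)
        return frag, f"{label_prefix}:{row.feature_id}"

    def draw_noise_insert():
        for _ in range(200):
            ln = int(rng.choice(lengths, p=length_p))
            seq = _random_seq(rng, ln)
            if seq not in genome and seq not in genome_rc:
                return seq, "noise"
        raise RuntimeError("could not draw a genome-absent noise insert")

    libraries = []
    for lib_idx, (lib, n_reads) in enumerate(zip("AB", config.library_sizes)):
        expected = np.array([a[2 + lib_idx] / 1e6 * n_reads for a in arms])
        if expected.sum() > n_reads:
            raise ValueError(
                "configured miRNA TPMs exceed the library size; lower the "
                "abundances or raise library_sizes"
            )
        resid = n_reads - expected.sum()
        g_w = config.genic_weight if len(genic_feats) else 0.0
        nc_w = config.ncrna_weight if len(ncrna_feats) else 0.0
        w = nc_w + g_w + config.noise_weight
        comp_expected = np.concatenate(
            [
                expected,
                [
                    resid * (nc_w / w if w > 0 else 0.0),
                    resid * (g_w / w if w > 0 else 0.0),
                    resid * (config.noise_weight / w if w > 0 else 1.0),
                ],
            ]
        )
        if n_reads > 0:
            counts = rng.multinomial(n_reads, comp_expected / comp_expected.sum())
        else:
            counts = np.zeros(len(comp_expected), dtype=int)
        records = []
        provenance = []
        serial = 0

        def emit(insert, label):
            nonlocal serial
            serial += 1
            read = _make_read(insert, config.adapter, config.read_length)
            if config.error_rate > 0:
                read = _mutate(rng, read, config.error_rate)
            records.append(
                (f"sim{lib}_{serial:07d}", read, "I" * config.read_length)
            )
            provenance.append(label)

        for (label, insert, _, _), c in zip(arms, counts[: len(arms)]):
            for _ in range(int(c)):
                emit(insert, label)
        for _ in range(int(counts[len(arms)])):
            insert, label = draw_fragment(ncrna_feats, "ncrna")
            emit(insert, label)
        for _ in range(int(counts[len(arms) + 1])):
            insert, label = draw_fragment(genic_feats, "genic")
            emit(insert, label)
        for _ in range(int(counts[len(arms) + 2])):
            insert, label = draw_noise_insert()
            emit(insert, label)
        sim.truth.provenance[lib] = provenance
        libraries.append(records)

    if outdir is not None:
        outdir = ensure_dir(outdir)
        write_fastq(libraries[0], outdir / "lib_A.fastq")
        write_fastq(libraries[1], outdir / "lib_B.fastq")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(sim.truth.provenance, fh, sort_keys=True)
    return libraries[0], libraries[1]


def _mutate(rng, read: str, rate: float) -> str:
    chars = list(read)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(_BASES[int(rng.integers(0, 4))])
    return "".join(chars)


def simulate_two_library_counts(
    tpm_a: np.ndarray,
    log2_fc: np.ndarray,
    library_sizes: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Count-level two-library draw for testing the DE machinery.

    Counts per library are multinomial over the features plus a filler
    component absorbing the residual library mass, so column sums equal the
    library sizes exactly.
    """
    tpm_a = np.asarray(tpm_a, dtype=float)
    tpm_b = tpm_a * 2.0 ** np.asarray(log2_fc, dtype=float)
    out = []
    for tpm, n in zip((tpm_a, tpm_b), library_sizes):
        p = tpm / 1e6
        filler = 1.0 - p.sum()
        if filler < 0:
            raise ValueError("TPMs exceed 1e6")
        counts = rng.multinomial(n, np.concatenate([p, [filler]]))
        out.append(counts[:-1])
    return out[0], out[1]


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "library_sizes" in d:
        d["library_sizes"] = tuple(d["library_sizes"])
    if "insert_length_dist" in d:
        d["insert_length_dist"] = {int(k): float(v) for k, v in d["insert_length_dist"].items()}
    if "log2_fc_table" in d:
        d["log2_fc_table"] = {str(k): float(v) for k, v in d["log2_fc_table"].items()}
    if "mirna_tpm_range" in d:
        d["mirna_tpm_range"] = tuple(d["mirna_tpm_range"])
    return SimConfig(**d)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
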