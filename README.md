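# mirseqkit

Small RNA-seq miRNA profiling between two libraries, end to end and fully
offline: a seeded synthetic study generator, read cleaning and tag
collapsing, priority-rule genome annotation, known-miRNA quantification,
novel-miRNA hairpin prediction with an in-package MFE folder, exact
two-library differential expression with Benjamini–Hochberg correction,
consensus seed-match target prediction, and hypergeometric term enrichment.

The intended workload is the classic drug-resistance contrast: library A is
a parental cell line, library B its resistant derivative, and the question
is which miRNAs change and what they target. Because real deep-sequencing
runs are not recomputable at desk scale, the package ships a generator that
plants miRNA stem-loops (some deliberately left out of the annotation) with
known abundances and fold changes, so every stage can be verified against
ground truth.

## Quick start

```python
from mirseqkit import RunConfig, run_pipeline
from mirseqkit.simulate import SimConfig

cfg = RunConfig(
    sim=SimConfig(
        genome_length=40_000,
        n_known_mirnas=8,
        n_hidden_hairpins=4,
        library_sizes=(20_000, 20_000),
        log2_fc_table={"mir-1": 3.0, "mir-2": -3.0, "hidden-1": 2.5},
        seed=5,
    ),
    seed=5,
)
run_pipeline(cfg, "example_run")
```

which prints nothing but writes a run directory; `example_run/report.md`
then contains (abridged, exactly reproducible with the seed above):

```
## Library cleaning
- library A: 20000 raw reads, 20000 clean reads (dimer 0, no-adapter 0, short 0, long 0)
- modal insert length: 22 nt
## Annotation (unique tags / reads A / reads B)
- known_miRNA: 16 / 4369 / 7022
- unannotated: 8 / 2199 / 7014
- rRNA QC A: 0.268 (PASS)
## Known and novel miRNAs
- mature miRNAs detected: A=16, B=16, shared=16
- novel miRNAs called: 4
- known DE: 2 up, 2 down (0 / 0 beyond 16-fold)
- novel DE: 1 up, 0 down
## Targets and enrichment
- consensus target genes: 14
- significantly enriched terms: 2
```

The four novel calls are the four planted hidden hairpins; the 2+2 known DE
calls are the two arms each of `mir-1` (planted up) and `mir-2` (planted
down); the novel up-call is `hidden-1`.

The same run from the shell:

```bash
smallrna run-all --outdir example_run --seed 5
smallrna simulate --outdir run2 --config run.yaml   # or stage by stage
smallrna clean    --outdir run2
```

Stages read and write plain-text files (TSV/FASTA/GFF3/BED/JSON) in the run
directory, so any stage can be re-run or swapped; reruns with the same
config are byte-identical.

## The stages

| stage    | what it does | key outputs |
|----------|--------------|-------------|
| simulate | genome with planted stem-loops + two FASTQ libraries | `genome.fa`, `features.gff3`, `lib_A/B.fastq`, `ground_truth.tsv` |
| clean    | adapter trim, Q20/N filters, 18–30 nt retention, tag collapse | `tags.tsv`, `qc_clean.json`, `length_histogram.tsv` |
| annotate | exact mapping + priority rule (rRNA-class > miRNA > repeat > exon > intron) | `annotation.tsv`, `category_counts.tsv`, `qc_rrna.json` |
| quantify | mature/precursor counts with a 2-nt isomiR window, TPM | `known_mirna_counts.tsv` |
| novel    | cluster unannotated tags, fold windows, gate on shape / MFE < −20 / Dicer ≥ 0.7 / ≥ 1 TPM | `novel_candidates.tsv`, `novel_mirna.bed` |
| de       | exact conditional binomial test, BH, call at adj. p < 0.05 and ≥ 2-fold | `de_known.tsv`, `de_summary.json` |
| targets  | 4 seed-match methods, ≥ 3-of-4 consensus | `targets.tsv` |
| enrich   | hypergeometric term enrichment, Bonferroni | `enrichment.tsv` |

`examples/` contains one narrative script per capability
(`python examples/01_simulate_and_clean.py`, …). `docs/methods.md` describes
the models, defaults and limitations.

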