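# Methods

This note records the models implemented by `mirseqkit`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions. Problem sizes quoted here
(genome lengths, library sizes) are the package's own choices for desk-scale
verification, not properties of any particular dataset.

## Synthetic study generator (`mirseqkit.simulate`)

The generator builds one chromosome of i.i.d. random sequence and plants
features into it with a non-overlap buffer of 20 nt:

* **miRNA stem-loops** — a designed 22-nt mature 5p arm (GC fraction 0.55,
  first base `T` with probability `first_base_u_prob`, default 0.8, matching
  the uridine bias of real Dicer products), a 12-nt loop, and the exact
  reverse complement of the arm as the 3p arm. A perfect 22-bp stem folds
  far below the −20 kcal/mol gate, so planted precursors are unambiguous
  positives. The 12-nt loop deliberately exceeds the default cluster merge
  distance (10 nt) so each arm forms its own read cluster and the Dicer
  5′-homogeneity gate is evaluated per arm.
* **Hidden hairpins** — identical construction, written into the genome but
  omitted from the GFF3: the planted truth set for novel-miRNA discovery.
* **Housekeeping ncRNAs** (rRNA/tRNA/snRNA/snoRNA/scRNA, alternating
  GenBank/Rfam source tags), **repeats**, and **gene models**
  (exon–intron–exon on a random strand).
* **3′UTRs and terms** — a separate UTR FASTA (default 120 genes × 400 nt)
  with an exact 8mer site for each known miRNA planted into a block of
  target genes, plus a gene→term table in which one reserved term per miRNA
  annotates its planted targets. This gives the target/enrichment stages
  real signal against a random background.

Two libraries of 50-nt reads are then drawn. Expected mature-arm counts are
`library_size × TPM / 1e6`, with library B scaled by `2**log2FC` from
`log2_fc_table`. Per-arm TPMs are log-uniform in `mirna_tpm_range` (default
5 000–50 000) and compositionally rescaled so the per-library total stays
under `max_total_mirna_tpm` (default 700 000), keeping the library
miRNA-dominated, as in a size-selected small-RNA prep, while leaving room
for the other read classes. The residual read mass is split
ncRNA fragments : repeat/exon/intron fragments : genome-absent noise at
weights 0.10 : 0.03 : 0.12 (renormalized). Fragments are drawn from
annotated loci with the study's insert-length distribution and are sense to
the source transcript with probability 0.9; noise inserts are
rejection-sampled to occur nowhere in the genome on either strand, so they
are unmappable by construction. Per-read source counts are drawn from one
multinomial, so emitted totals equal the configured library sizes exactly.
Reads are insert + 3′ adapter, cycled and truncated to 50 nt. Everything is
driven by `numpy.random.default_rng(seed)`; reruns are byte-identical.

Not emulated: sequencing errors beyond an optional uniform substitution rate
(default 0), quality-score variation (all bases Q40), PCR duplication bias,
multi-chromosome genomes, isomiR 3′ trimming/tailing variants, and
cross-mapping between paralogous precursors.

## Read cleaning (`mirseqkit.reads`)

Reads failing Q20 at any of the first 36 cycles are dropped. The 3′ adapter
is located by scoring every start position leaving ≥ 6 adapter bases as
`matches − 2·mismatches` over the overlapping adapter prefix, discarding
candidates above a 10% mismatch rate; ties go to the leftmost position, and
a leftmost perfect full-length occurrence is provably optimal (fast path).
An adapter at position 0 is an adapter-dimer contaminant. Inserts with `N`
are dropped; retention is 18–30 nt inclusive. Rejection-class counters
always conserve the input count. Cleaned inserts collapse to unique tags
with per-library counts — the atomic unit of all later stages.

## Annotation (`mirseqkit.annotate`)

Tags map by exact full-length match on both strands via a 12-mer seed index.
Each tag receives one category under the priority rule

```
rRNA-class ncRNA (GenBank > Rfam) > known miRNA > repeat > exon > intron
```

with sense preferred over antisense for exon/intron, `unannotated` for
mapped tags overlapping nothing, and `unmapped` otherwise. miRNA assignment
is strand-specific; the best category over all of a tag's hits wins. The
read-weighted rRNA-class fraction must stay below 40% per library (QC flag,
fail at ≥ 0.40). Known-miRNA quantification counts a tag toward a mature
arm when its 5′ end lies within a 2-nt isomiR window of the annotated
mature 5′ end inside the precursor, on the same strand; precursor-only tags
count toward the precursor. TPM is `count / clean_reads × 1e6`.

## RNA folding (`mirseqkit.fold`)

Minimum-free-energy folding under a self-contained nearest-neighbour model:
a symmetric stacking table over the six canonical/wobble pairs, hairpin
closure penalties by loop size, and bulge/internal-loop penalties, with
logarithmic extrapolation beyond the tabulated sizes. Multibranch and
exterior loops contribute 0; pseudoknots are excluded; the minimum hairpin
loop is 3 nt. Interior loops with more than 12 unpaired bases are disallowed
**as part of the model definition** — not as a search shortcut — so the
Zuker-style dynamic program, the loop-decomposition rescoring of any
explicit structure, and an exhaustive enumeration oracle all score the
identical model and agree exactly. Energies are handled internally in
integer tenths of kcal/mol, making DP comparisons exact; ties are broken
toward fewer pairs. Parameter values are Turner-style magnitudes bundled in
`mirseqkit/data/energy_params.yaml`; absolute MFEs therefore differ from
ViennaRNA's, but qualitative classifications (stable designed stems vs
random sequence) agree, which is all the −20 kcal/mol gate needs.

## Novel miRNA prediction (`mirseqkit.novel`)

Unannotated tag hits merge into strand-specific clusters when the gap is
≤ 10 nt. Each cluster with ≥ 3 reads is tried as the 5′ and as the 3′ arm of
a precursor by extracting the corresponding genomic window (default 70-nt
flank, clipped at chromosome ends, reverse-complemented for minus-strand
clusters) and folding it. Gates:

1. **hairpin shape** — ≥ 14 arm bases paired, all partners outside the arm
   with monotone (nested) positions, ≤ 4 unpaired arm bases excluding the
   2-nt 3′ overhang, terminal loop 3–20 nt;
2. **MFE strictly below −20 kcal/mol**;
3. **Dicer consistency** — the read-weighted modal 5′ end holds ≥ 0.7 of the
   cluster's reads;
4. **expression** — ≥ 1 TPM (inclusive), by default in both libraries
   (`require_both_samples=False` relaxes to either).

The verdict is the conjunction; accepted windows overlapping an already
accepted one (the two arms of one hairpin) deduplicate toward the more
abundant cluster, and survivors are named `novel-miR-1..N` by descending
total count.

## Differential expression (`mirseqkit.de`)

For each miRNA with `n = count_A + count_B > 0`, under the null of equal
relative abundance `count_B | n ~ Binomial(n, q)` with
`q = total_B / (total_A + total_B)`. The two-sided p-value sums all outcomes
no more likely than the observed one (minimum-likelihood convention), with a
relative slack of 1e-7 when comparing float likelihoods to protect exact
ties. P-values are adjusted with an in-package Benjamini–Hochberg step-up;
calls require adjusted p < 0.05 **and** |log2 TPM fold change| ≥ 1. Zero
TPMs (and only zeros) are floored at 0.01 before the ratio so
library-specific miRNAs get a large finite fold change. The ">16-fold"
summary counts strict |log2FC| > 4.

## Targets and enrichment (`mirseqkit.targets`)

Four in-house seed-match parameterizations stand in for independent
prediction tools so the ≥ 3-of-4 consensus rule is testable offline:
M1 = 7mer-m8; M2 = 8mer; M3 = 7mer-A1 **or** 7mer-m8 with ≥ 4 contiguous
complementary bases from miRNA positions 13–17 within 12 nt upstream of the
site; M4 = 7mer-m8 whose seed-extended contiguous duplex scores
≤ −14 kcal/mol under the folding module's stack table. Externally produced
per-tool gene lists can substitute for any method. Per-gene support is the
union over sites; genes with ≥ 3 supporting methods are retained. Enrichment
is the hypergeometric upper tail per term over a user-supplied gene→term map
with Bonferroni correction across the terms tested; `percentage` is the
term's target count over the number of annotated target genes.

## Numerical conventions and limitations

* All coordinates are 0-based half-open internally; GFF3 I/O converts to and
  from the 1-based inclusive convention.
* Folding energies are integer decikcal internally; p-values are float64 —
  extremely significant tests can underflow to 0.0, which renders as
  `0.00E+00` in published-style tables.
* The exact test conditions on per-miRNA totals and ignores biological
  (replicate) variance — with one library per condition there is no
  dispersion to estimate, so its p-values are anti-conservative for noisy
  biology; this matches the single-replicate design it reproduces.
* The folder is O(n²·c) per sequence with a 200-nt default cap — intended
  for precursor windows, not transcripts.
* Exact full-length mapping has no mismatch tolerance; reads with
  sequencing errors in the insert become `unmapped` rather than mismapped.
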