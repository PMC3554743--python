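"""File-format helpers: FASTA/FASTQ, GFF3 feature tables, collapsed-tag FASTA.

Feature tables are pandas DataFrames with 0-based half-open ``start``/``end``
internally; GFF3 on disk is 1-based inclusive and converted on read/write.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")

FEATURE_COLUMNS = [
    "chrom",
    "source",
    "type",
    "start",
    "end",
    "strand",
    "feature_id",
    "parent",
]


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path):
    """Yield (read_id, sequence, quality) tuples."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield rec.id, str(rec.seq).upper(), quals


def write_fastq(records, path) -> None:
    """Write (read_id, sequence, quality-string) records as Sanger FASTQ."""
    with open(path, "w") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_gff3(path) -> pd.DataFrame:
    """Read GFF3 into the internal feature table (0-based half-open)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "chrom": f[0],
                    "source": f[1],
                    "type": f[2],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                    "feature_id": attrs.get("ID", ""),
                    "parent": attrs.get("Parent", ""),
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write the internal feature table as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            attrs = f"ID={row.feature_id}"
            if row.parent:
                attrs += f";Parent={row.parent}"
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        row.source,
                        row.type,
                        str(row.start + 1),
                        str(row.end),
                        ".",
                        row.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_tag_fasta(tags: pd.DataFrame, path) -> None:
    """Collapsed tags as FASTA with ``>tagN_countA_countB`` headers."""
    with open(path, "w") as fh:
        for n, row in enumerate(tags.itertuples(index=False), start=1):
            fh.write(f">tag{n}_{row.count_a}_{row.count_b}\n{row.sequence}\n")


def read_tag_fasta(path) -> pd.DataFrame:
    rows = []
    for name, seq in read_fasta(path).items():
        parts = name.split("_")
        rows.append(
            {"sequence": seq, "count_a": int(parts[-2]), "count_b": int(parts[-1])}
        )
    return pd.DataFrame(rows, columns=["sequence", "count_a", "count_b"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED6 from a frame with chrom/start/end/name/score/strand columns."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{row.score}\t{row.strand}\n"
            )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
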