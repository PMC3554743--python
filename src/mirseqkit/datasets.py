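"""Reported results from the HepG2 vs HepG2/DOX deep-sequencing comparison.

The published profiling study that this pipeline re-implements contrasted a
doxorubicin-resistant hepatocellular carcinoma line (HepG2/DOX, "library B")
with its parent (HepG2, "library A").  Its printed result tables — the most
significant known-miRNA calls, the significant novel-miRNA calls, the
headline significant-miRNA totals, and the exon sense/antisense mapping
counts — are bundled here so the package's filter and summary arithmetic can
be exercised against real reported values without the deposited raw data.

Fold changes are log2((HepG2/DOX)/HepG2); p-values are BH-adjusted.
"""

from __future__ import annotations

import pandas as pd

#: significant known miRNAs: 23 up- and 246 down-regulated were reported
REPORTED_KNOWN_UP = 23
REPORTED_KNOWN_DOWN = 246

#: most significantly differentially expressed known miRNAs (printed table)
_KNOWN_DE_ROWS = [
    ("hsa-miR-181a-3p", 9.04, "Up", 1.56e-23),
    ("hsa-miR-3660", 7.87, "Up", 1.95e-11),
    ("hsa-miR-2682-5p", 7.77, "Up", 7.78e-11),
    ("hsa-miR-551b-3p", 7.39, "Up", 9.63e-09),
    ("hsa-miR-3117-3p", 7.26, "Up", 3.73e-08),
    ("hsa-miR-551b-5p", 7.11, "Up", 1.49e-07),
    ("hsa-miR-548h-5p", 6.95, "Up", 5.93e-07),
    ("hsa-miR-296-3p", 6.60, "Up", 8.05e-29),
    ("hsa-miR-4488", 5.95, "Up", 4.10e-35),
    ("hsa-miR-296-5p", 5.84, "Up", 3.88e-78),
    ("hsa-miR-4454", 5.19, "Up", 3.07e-85),
    ("hsa-miR-4687-3p", 4.37, "Up", 8.32e-26),
    ("hsa-miR-3654", 3.38, "Up", 1.21e-25),
    ("hsa-miR-577", 2.94, "Up", 8.64e-05),
    ("hsa-miR-4508", 2.90, "Up", 5.94e-06),
    ("hsa-miR-3687", 2.49, "Up", 2.04e-05),
    ("hsa-miR-4448", 2.45, "Up", 1.66e-04),
    ("hsa-miR-4426", 2.23, "Up", 3.53e-05),
    ("hsa-miR-720", 2.08, "Up", 1.21e-05),
    ("hsa-miR-4485", 1.71, "Up", 6.14e-08),
    ("hsa-miR-877-5p", 1.68, "Up", 1.92e-82),
    ("hsa-miR-3679-5p", 1.45, "Up", 5.53e-04),
    ("hsa-miR-21-3p", 1.40, "Up", 7.87e-13),
    ("hsa-miR-338-3p", -11.63, "Down", 4.47e-133),
    ("hsa-miR-486-3p", -8.90, "Down", 2.14e-21),
    ("hsa-miR-944", -8.39, "Down", 1.61e-15),
    ("hsa-miR-2277-5p", -8.01, "Down", 2.67e-12),
    ("hsa-miR-338-5p", -8.01, "Down", 2.68e-12),
    ("hsa-miR-139-3p", -7.96, "Down", 9.21e-75),
    ("hsa-miR-4427", -7.36, "Down", 1.58e-08),
    ("hsa-miR-3186-3p", -7.01, "Down", 4.40e-07),
    ("hsa-miR-1269b", -6.74, "Down", 3.15e-06),
    ("hsa-miR-3674", -6.74, "Down", 3.16e-06),
    ("hsa-miR-3910", -6.74, "Down", 3.17e-06),
    ("hsa-miR-642a-3p", -6.74, "Down", 5.10e-32),
    ("hsa-miR-486-5p", -6.46, "Down", 2.81e-100),
    ("hsa-miR-203", -6.30, "Down", 3.19e-89),
    ("hsa-miR-1277-3p", -6.16, "Down", 3.01e-41),
    ("hsa-miR-1277-5p", -5.90, "Down", 3.84e-18),
    ("hsa-miR-1250", -5.71, "Down", 2.05e-169),
    ("hsa-miR-139-5p", -5.46, "Down", 3.71e-25),
    ("hsa-miR-335-5p", -5.26, "Down", 2.00e-41),
    ("hsa-miR-362-3p", -5.01, "Down", 3.36e-10),
    ("hsa-miR-1255a", -4.92, "Down", 1.25e-62),
    ("hsa-miR-3622a-5p", -4.83, "Down", 4.30e-09),
    ("hsa-miR-1293", -4.67, "Down", 2.87e-08),
    ("hsa-miR-2116-3p", -4.64, "Down", 3.67e-14),
    ("hsa-miR-365a-3p", -4.52, "Down", 8.20e-62),
    ("hsa-miR-365b-3p", -4.52, "Down", 8.29e-62),
    ("hsa-miR-4501", -4.22, "Down", 2.27e-06),
    ("hsa-miR-196a-3p", -4.14, "Down", 4.15e-06),
    ("hsa-miR-500a-5p", -4.01, "Down", 2.94e-09),
    ("hsa-miR-500b", -4.01, "Down", 2.94e-09),
]

#: significant novel-miRNA calls (printed table; ids as printed)
_NOVEL_DE_ROWS = [
    ("hsa-novel-mir-27", 10.32, "Up", 7.84e-55),
    ("hsa-novel-miR-35", 9.95, "Up", 5.69e-43),
    ("hsa-novel-miR-14", 9.59, "Up", 7.59e-34),
    ("hsa-novel-mir-8", 9.31, "Up", 4.43e-28),
    ("hsa-novel-miR-12", 8.84, "Up", 8.36e-21),
    ("hsa-novel-miR-25", 7.99, "Up", 2.48e-12),
    ("hsa-novel-mir-15", 7.57, "Up", 1.23e-09),
    ("hsa-novel-miR-17", 1.39, "Up", 1.75e-03),
    ("hsa-novel-miR-26", 1.12, "Up", 1.58e-08),
    ("hsa-novel-miR-43", -10.14, "Down", 3.29e-48),
    ("hsa-novel-miR-65", -9.644, "Down", 1.24e-34),
    ("hsa-novel-miR-51", -8.12, "Down", 3.59e-13),
    ("hsa-novel-miR-41", -8.08, "Down", 7.06e-13),
    ("hsa-novel-miR-64", -7.48, "Down", 4.18e-09),
    ("hsa-novel-miR-50", -7.29, "Down", 3.06e-08),
    ("hsa-novel-miR-72", -7.29, "Down", 3.05e-08),
    ("hsa-novel-miR-71", -7.23, "Down", 5.87e-08),
    ("hsa-novel-miR-58", -7.08, "Down", 2.25e-07),
    ("hsa-novel-miR-57", -6.74, "Down", 3.13e-06),
    ("hsa-novel-miR-13", -2.82, "Down", 1.41e-21),
    ("hsa-novel-miR-19", -1.04, "Down", 4.77e-05),
    ("hsa-novel-miR-5", -1.01, "Down", 2.18e-06),
]

#: unique-tag counts mapped to exon regions, by strand relative to the exon
EXON_STRAND_UNIQUE_TAGS = {
    "HepG2": {"sense": 25_847, "antisense": 2_332},
    "HepG2/DOX": {"sense": 173_619, "antisense": 1_546},
}

_COLS = ["mirna_id", "log2_fc", "direction", "p_adj"]


def reported_known_de_table() -> pd.DataFrame:
    """The printed table of most significant known-miRNA calls."""
    return pd.DataFrame(_KNOWN_DE_ROWS, columns=_COLS)


def reported_novel_de_table() -> pd.DataFrame:
    """The printed table of significant novel-miRNA calls."""
    return pd.DataFrame(_NOVEL_DE_ROWS, columns=_COLS)


def count_over_fold(table: pd.DataFrame, min_log2_fc: float = 4.0) -> dict[str, int]:
    """How many printed rows exceed a |log2 fold change| cutoff, by direction.

    With the default cutoff this is the ">16-fold" summary rule.
    """
    up = int(((table["direction"] == "Up") & (table["log2_fc"] > min_log2_fc)).sum())
    down = int(
        ((table["direction"] == "Down") & (table["log2_fc"] < -min_log2_fc)).sum()
    )
    return {"up": up, "down": down}


def apply_significance_filter(
    table: pd.DataFrame, alpha: float = 0.05, min_fold: float = 2.0
) -> dict[str, int]:
    """Apply the adjusted-p and fold-change gates to a printed table."""
    import numpy as np

    thresh = np.log2(min_fold)
    sig = table[table["p_adj"] < alpha]
    return {
        "up": int(((sig["direction"] == "Up") & (sig["log2_fc"] >= thresh)).sum()),
        "down": int(((sig["direction"] == "Down") & (sig["log2_fc"] <= -thresh)).sum()),
    }


def exon_strand_ratios() -> dict[str, int]:
    """Rounded sense:antisense unique-tag ratios per sample."""
    return {
        sample: round(c["sense"] / c["antisense"])
        for sample, c in EXON_STRAND_UNIQUE_TAGS.items()
    }
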