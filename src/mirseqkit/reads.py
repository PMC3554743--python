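"""Read cleaning, tag collapsing and library summary statistics.

A raw 50-nt read is quality-checked, its 3' adapter located and removed,
and the remaining insert kept when it is 18-30 nt of unambiguous sequence.
Cleaned inserts are collapsed to unique *tags* with per-library read counts
— the atomic unit of every later stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ADAPTER_3P

MIN_INSERT = 18
MAX_INSERT = 30

TAG_COLUMNS = ["sequence", "count_a", "count_b"]


@dataclass
class TrimResult:
    insert: str | None
    reason: str | None = None  # "no_adapter" | "adapter_dimer"
    adapter_start: int = -1


def trim_adapter(
    read: str,
    adapter: str = ADAPTER_3P,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> TrimResult:
    """Locate the best 3' adapter prefix match and return the insert.

    Every start position leaving at least ``min_overlap`` adapter bases is
    scored as matches - 2*mismatches over the overlapping adapter prefix;
    candidates above the mismatch-rate ceiling are discarded and ties go to
    the leftmost position.  An adapter starting at position 0 marks an
    adaptor-adaptor contaminant (empty insert).
    """
    if not read:
        raise ValueError("empty read")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = read.upper()
    # fast path: a leftmost perfect full-length occurrence is always optimal
    exact = read.find(adapter)
    if exact != -1:
        if exact == 0:
            return TrimResult(None, reason="adapter_dimer", adapter_start=0)
        return TrimResult(read[:exact], adapter_start=exact)
    best_score, best_pos = None, -1
    for pos in range(0, len(read) - min_overlap + 1):
        m = min(len(adapter), len(read) - pos)
        ceiling = int(max_mismatch_rate * m)
        mism = 0
        for a, b in zip(read[pos : pos + m], adapter[:m]):
            if a != b:
                mism += 1
                if mism > ceiling:
                    break
        if mism > max_mismatch_rate * m:
            continue
        score = (m - mism) - 2 * mism
        if best_score is None or score > best_score:
            best_score, best_pos = score, pos
    if best_score is None:
        return TrimResult(None, reason="no_adapter")
    if best_pos == 0:
        return TrimResult(None, reason="adapter_dimer", adapter_start=0)
    return TrimResult(read[:best_pos], adapter_start=best_pos)


def quality_ok(quals, min_quality: int = 20, n_cycles: int = 36) -> bool:
    """True when no base call in the first ``n_cycles`` falls below Q."""
    return all(q >= min_quality for q in quals[:n_cycles])


def length_filter(
    inserts, min_len: int = MIN_INSERT, max_len: int = MAX_INSERT
) -> tuple[list[str], int, int]:
    """Retain inserts with min_len <= length <= max_len (inclusive)."""
    kept, n_short, n_long = [], 0, 0
    for ins in inserts:
        if len(ins) < min_len:
            n_short += 1
        elif len(ins) > max_len:
            n_long += 1
        else:
            kept.append(ins)
    return kept, n_short, n_long


@dataclass
class CleanResult:
    inserts: list[str]
    counters: dict[str, int] = field(default_factory=dict)


def clean_reads(
    records,
    adapter: str = ADAPTER_3P,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_quality: int = 20,
    quality_cycles: int = 36,
    min_len: int = MIN_INSERT,
    max_len: int = MAX_INSERT,
) -> CleanResult:
    """Full cleaning cascade for one library of (id, seq, qual) records.

    Counter conservation holds at every stage:
    ``n_input = n_low_quality + n_adapter_dimer + n_no_adapter + n_with_n
    + n_too_short + n_too_long + n_clean``.
    """
    c = Counter()
    trimmed = []
    for _, seq, qual in records:
        c["n_input"] += 1
        if isinstance(qual, str):
            qual = [ord(ch) - 33 for ch in qual]
        if not quality_ok(qual, min_quality, quality_cycles):
            c["n_low_quality"] += 1
            continue
        res = trim_adapter(seq, adapter, min_overlap, max_mismatch_rate)
        if res.insert is None:
            c["n_adapter_dimer" if res.reason == "adapter_dimer" else "n_no_adapter"] += 1
            continue
        if "N" in res.insert:
            c["n_with_n"] += 1
            continue
        trimmed.append(res.insert)
    kept, n_short, n_long = length_filter(trimmed, min_len, max_len)
    c["n_too_short"] = n_short
    c["n_too_long"] = n_long
    c["n_clean"] = len(kept)
    return CleanResult(inserts=kept, counters=dict(c))


def collapse_tags(inserts_a, inserts_b) -> pd.DataFrame:
    """Collapse cleaned inserts from both libraries to unique tags.

    Returns a frame with columns sequence/count_a/count_b, sorted by total
    count descending then sequence (stable across runs).
    """
    ca, cb = Counter(inserts_a), Counter(inserts_b)
    seqs = sorted(set(ca) | set(cb))
    df = pd.DataFrame(
        {
            "sequence": seqs,
            "count_a": [ca.get(s, 0) for s in seqs],
            "count_b": [cb.get(s, 0) for s in seqs],
        }
    )
    total = df["count_a"] + df["count_b"]
    df = df.iloc[np.lexsort((df["sequence"], -total))].reset_index(drop=True)
    return df[TAG_COLUMNS]


def expand_tags(tags: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Inverse of collapse: the multiset of inserts per library."""
    a, b = [], []
    for row in tags.itertuples(index=False):
        a.extend([row.sequence] * row.count_a)
        b.extend([row.sequence] * row.count_b)
    return a, b


@dataclass
class LibrarySummary:
    total_clean_reads: int
    length_histogram: pd.Series  # reads per insert length 18..30
    first_base_by_length: pd.DataFrame  # base x length, read-weighted
    position_base_composition: pd.DataFrame  # base x position(1..30), read-weighted
    unique_common: float
    unique_specific: float
    total_common: float
    total_specific: float
    qc_warning: str | None = None


def _one_library_summary(tags, counts, common_mask, n_unique_all, total_all):
    bases = list("ACGT")
    base_idx = {b: i for i, b in enumerate(bases)}
    hist_arr = np.zeros(MAX_INSERT - MIN_INSERT + 1, dtype=np.int64)
    fb_arr = np.zeros((4, MAX_INSERT - MIN_INSERT + 1), dtype=np.int64)
    comp_arr = np.zeros((4, MAX_INSERT), dtype=np.int64)
    for seq, cnt in zip(tags["sequence"], counts):
        if cnt == 0:
            continue
        ln = len(seq)
        if MIN_INSERT <= ln <= MAX_INSERT:
            hist_arr[ln - MIN_INSERT] += cnt
            fb_arr[base_idx[seq[0]], ln - MIN_INSERT] += cnt
        for pos, base in enumerate(seq):
            comp_arr[base_idx[base], pos] += cnt
    hist = pd.Series(hist_arr, index=range(MIN_INSERT, MAX_INSERT + 1))
    fb = pd.DataFrame(fb_arr, index=bases, columns=range(MIN_INSERT, MAX_INSERT + 1))
    comp = pd.DataFrame(comp_arr, index=bases, columns=range(1, MAX_INSERT + 1))
    present = counts > 0
    n_total = int(counts.sum())
    return LibrarySummary(
        total_clean_reads=n_total,
        length_histogram=hist,
        first_base_by_length=fb,
        position_base_composition=comp,
        unique_common=(present & common_mask).sum() / n_unique_all if n_unique_all else 0.0,
        unique_specific=(present & ~common_mask).sum() / n_unique_all if n_unique_all else 0.0,
        total_common=counts[common_mask].sum() / total_all if total_all else 0.0,
        total_specific=counts[~common_mask].sum() / total_all if total_all else 0.0,
        qc_warning=None if n_total else "empty library",
    )


def summarize_libraries(tags: pd.DataFrame) -> dict[str, LibrarySummary]:
    """Per-library summaries plus cross-library common/specific fractions.

    "Common" is sequence identity across libraries; fractions are computed
    both in unique-tag space (denominator: all unique tags) and read-weighted
    (denominator: all reads, both libraries), so
    ``common + specific_A + specific_B = 1`` in each space.
    """
    if len(tags) == 0:
        empty = LibrarySummary(
            0,
            pd.Series(0, index=range(MIN_INSERT, MAX_INSERT + 1)),
            pd.DataFrame(0, index=list("ACGT"), columns=range(MIN_INSERT, MAX_INSERT + 1)),
            pd.DataFrame(0, index=list("ACGT"), columns=range(1, MAX_INSERT + 1)),
            0.0,
            0.0,
            0.0,
            0.0,
            qc_warning="empty tag table",
        )
        return {"A": empty, "B": empty}
    ca = tags["count_a"].to_numpy()
    cb = tags["count_b"].to_numpy()
    common = (ca > 0) & (cb > 0)
    n_unique = len(tags)
    total_all = int(ca.sum() + cb.sum())
    return {
        "A": _one_library_summary(tags, ca, common, n_unique, total_all),
        "B": _one_library_summary(tags, cb, common, n_unique, total_all),
    }
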