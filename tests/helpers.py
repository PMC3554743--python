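"""Independent oracles used by the test-suite (and only by it).

Each oracle computes the quantity by direct definition — exhaustive
enumeration, exact rational arithmetic, or brute-force scanning — never by
calling the code path it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

from mirseqkit.fold import MIN_HAIRPIN, structure_energy


def enumerate_min_energy(seq: str, model) -> float:
    """Exhaustive-enumeration MFE: minimum loop-decomposition energy over
    every valid nested structure (including the empty one)."""

    def rec(i, j):
        if j - i < MIN_HAIRPIN + 1:
            return [[]]
        out = list(rec(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if model.pairable(seq[i], seq[k]):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append([(i, k)] + inner + rest)
        return out

    best = 0.0
    n = len(seq)
    for pairs in rec(0, n - 1):
        db = ["."] * n
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        e = structure_energy(seq, "".join(db), model)
        if e < best:
            best = e
    return best


def exact_two_sided_binomial(a: int, b: int, total_a: int, total_b: int) -> float:
    """Exact-rational minimum-likelihood two-sided binomial p-value.

    All pmf values share the denominator (total_a+total_b)**n, so likelihood
    comparison and summation stay in exact integer arithmetic.
    """
    n = a + b
    nums = [comb(n, k) * total_b**k * total_a ** (n - k) for k in range(n + 1)]
    p = Fraction(sum(x for x in nums if x <= nums[b]), (total_a + total_b) ** n)
    return float(min(Fraction(1), p))


def bh_definitional(p_values) -> list[float]:
    """adj_i = min over j with p_(j) >= rank of i of m * p_(j) / j, capped at 1."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = 1.0
        for later_pos in range(rank_pos, m):
            j = later_pos + 1
            cand = m * p_values[indexed[later_pos]] / j
            if cand < best:
                best = cand
        adj[i] = best
    return adj


def brute_force_merge(intervals, gap):
    """Reference interval merging: sort then sweep with the gap rule."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def brute_force_category(tag_hits, features, priority, ncrna_types):
    """Reference priority-rule category by scanning the raw feature rows."""
    best = "unmapped" if not tag_hits else "unannotated"
    for hit in tag_hits:
        for row in features.itertuples(index=False):
            if row.type == "gene" or row.chrom != hit.chrom:
                continue
            if row.end <= hit.start or hit.end <= row.start:
                continue
            if row.type in ncrna_types:
                cat = "rRNA_etc_GenBank" if row.source == "GenBank" else "rRNA_etc_Rfam"
            elif row.type in ("miRNA_precursor", "miRNA", "mature_miRNA"):
                if row.strand != hit.strand:
                    continue
                cat = "known_miRNA"
            elif row.type in ("repeat", "repeat_region"):
                cat = "repeat"
            elif row.type == "exon":
                cat = "exon_sense" if row.strand == hit.strand else "exon_antisense"
            elif row.type == "intron":
                cat = "intron_sense" if row.strand == hit.strand else "intron_antisense"
            else:
                continue
            if priority.index(cat) < priority.index(best):
                best = cat
    return best
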