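"""Novel miRNA prediction from unannotated mapped tags.

Unannotated tag hits are merged into strand-specific genomic read clusters;
each cluster is treated in turn as the 5' and the 3' mature arm of a
putative precursor, the corresponding genomic window is folded, and four
gates decide the call:

* hairpin shape — the arm sits in a stem of sufficient paired length with a
  3-20 nt terminal loop and at most a few unpaired arm bases,
* minimum free energy strictly below -20 kcal/mol,
* Dicer-cleavage consistency — most reads in the stack share one 5' end,
* detectable expression (>= 1 TPM), by default required in both libraries.

The verdict is the conjunction of the four flags; accepted candidates are
named novel-miR-1..N by descending total read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fold import EnergyModel, FoldResult, fold_rna
from .io import revcomp
from .annotate import GenomeHit

MFE_THRESHOLD = -20.0  # kcal/mol, strict
TPM_THRESHOLD = 1.0  # inclusive, per library


@dataclass
class ClusterMember:
    sequence: str
    start: int
    end: int
    count_a: int
    count_b: int

    def five_prime(self, strand: str) -> int:
        return self.start if strand == "+" else self.end - 1


@dataclass
class Cluster:
    chrom: str
    strand: str
    start: int
    end: int
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def count_a(self) -> int:
        return sum(m.count_a for m in self.members)

    @property
    def count_b(self) -> int:
        return sum(m.count_b for m in self.members)


def cluster_unannotated(
    annotated: pd.DataFrame,
    hits_by_seq: dict[str, list[GenomeHit]],
    merge_distance: int = 10,
) -> list[Cluster]:
    """Merge unannotated tag hits (same strand, gap <= merge_distance)."""
    placed: dict[tuple[str, str], list[ClusterMember]] = {}
    for row in annotated[annotated["category"] == "unannotated"].itertuples(index=False):
        for hit in hits_by_seq.get(row.sequence, []):
            placed.setdefault((hit.chrom, hit.strand), []).append(
                ClusterMember(row.sequence, hit.start, hit.end, row.count_a, row.count_b)
            )
    clusters: list[Cluster] = []
    for (chrom, strand), members in sorted(placed.items()):
        members.sort(key=lambda m: (m.start, m.end))
        current: Cluster | None = None
        for m in members:
            if current is not None and m.start <= current.end + merge_distance:
                current.end = max(current.end, m.end)
                current.members.append(m)
            else:
                current = Cluster(chrom, strand, m.start, m.end, [m])
                clusters.append(current)
    return clusters


@dataclass
class PrecursorWindow:
    """A candidate precursor window in transcript (5'->3') orientation."""

    role: str  # arm hypothesis: "5p" or "3p"
    genomic_start: int
    genomic_end: int
    sequence: str
    arm_start: int  # cluster span, window coordinates
    arm_end: int


def extract_precursor(
    cluster: Cluster,
    genome: str,
    flank_up: int = 70,
    flank_down: int = 70,
) -> list[PrecursorWindow]:
    """Windows placing the read stack on the 5' arm and on the 3' arm.

    Windows running off the chromosome are clipped.  For minus-strand
    clusters the flanks are applied in transcript orientation and the
    sequence reverse-complemented.
    """
    n = len(genome)
    windows = []
    for role in ("5p", "3p"):
        if cluster.strand == "+":
            if role == "5p":
                gs, ge = cluster.start, min(n, cluster.end + flank_down)
            else:
                gs, ge = max(0, cluster.start - flank_up), cluster.end
            seq = genome[gs:ge]
            arm_start, arm_end = cluster.start - gs, cluster.end - gs
        else:
            if role == "5p":
                gs, ge = max(0, cluster.start - flank_down), cluster.end
            else:
                gs, ge = cluster.start, min(n, cluster.end + flank_up)
            seq = revcomp(genome[gs:ge])
            arm_start, arm_end = ge - cluster.end, ge - cluster.start
        windows.append(PrecursorWindow(role, gs, ge, seq, arm_start, arm_end))
    return windows


def dicer_consistency(cluster: Cluster, threshold: float = 0.7) -> tuple[float, bool]:
    """Read-weighted fraction sharing the modal 5' end; pass at >= threshold."""
    weights: dict[int, int] = {}
    total = 0
    for m in cluster.members:
        w = m.count_a + m.count_b
        weights[m.five_prime(cluster.strand)] = (
            weights.get(m.five_prime(cluster.strand), 0) + w
        )
        total += w
    if total == 0:
        return 0.0, False
    frac = max(weights.values()) / total
    return frac, frac >= threshold


def hairpin_shape(
    fold: FoldResult,
    arm_start: int,
    arm_end: int,
    min_paired: int = 14,
    loop_range: tuple[int, int] = (3, 20),
    max_unpaired_arm: int = 4,
) -> bool:
    """Does the folded window place the mature arm in a clean stem?

    Requires >= ``min_paired`` paired arm bases all pairing outside the arm
    with nested (monotone) partners, <= ``max_unpaired_arm`` unpaired arm
    bases (the 2-nt 3' overhang excluded), and a terminal loop within
    ``loop_range`` between the arm and its star arm.
    """
    partner: dict[int, int] = {}
    for i, j in fold.pairs():
        partner[i] = j
        partner[j] = i
    arm = range(arm_start, arm_end)
    paired = [(p, partner[p]) for p in arm if p in partner]
    if len(paired) < min_paired:
        return False
    # partners must all sit outside the arm (a stem, not arm self-structure)
    if any(arm_start <= q < arm_end for _, q in paired):
        return False
    # nested: partner positions monotone decreasing along the arm
    qs = [q for _, q in paired]
    if any(b >= a for a, b in zip(qs, qs[1:])):
        return False
    unpaired = [p for p in arm if p not in partner]
    # a 2-nt 3' overhang is expected from Dicer processing
    overhang = {arm_end - 1, arm_end - 2}
    if len([p for p in unpaired if p not in overhang]) > max_unpaired_arm:
        return False
    loop = min(abs(q - p) - 1 for p, q in paired)
    return loop_range[0] <= loop <= loop_range[1]


def call_novel(
    clusters: list[Cluster],
    genome: str,
    totals: tuple[int, int],
    mfe_threshold: float = MFE_THRESHOLD,
    min_tpm: float = TPM_THRESHOLD,
    require_both_samples: bool = True,
    dicer_threshold: float = 0.7,
    min_reads: int = 3,
    flank_up: int = 70,
    flank_down: int = 70,
    min_paired: int = 14,
    loop_range: tuple[int, int] = (3, 20),
    max_unpaired_arm: int = 4,
    model: EnergyModel | None = None,
) -> pd.DataFrame:
    """Evaluate every cluster against the four gates and name the calls.

    Returns one row per evaluated cluster with the chosen window, fold, per
    criterion flags, verdict (the AND of the flags) and, for accepted
    candidates, ids ``novel-miR-1..N`` assigned by descending total count.
    Overlapping accepted windows (the two arms of one hairpin) are
    deduplicated toward the more abundant cluster.
    """
    model = model or EnergyModel.default()
    total_a, total_b = totals
    rows = []
    for cluster in clusters:
        if cluster.count_a + cluster.count_b < min_reads:
            continue
        dicer_frac, dicer_pass = dicer_consistency(cluster, dicer_threshold)
        best = None
        for window in extract_precursor(cluster, genome, flank_up, flank_down):
            if len(window.sequence) < 20:
                continue
            fold = fold_rna(window.sequence, model=model)
            shape = hairpin_shape(
                fold,
                window.arm_start,
                window.arm_end,
                min_paired=min_paired,
                loop_range=loop_range,
                max_unpaired_arm=max_unpaired_arm,
            )
            key = (not shape, fold.mfe)  # prefer shape-pass, then lower MFE
            if best is None or key < best[0]:
                best = (key, window, fold, shape)
        if best is None:
            continue
        _, window, fold, shape = best
        tpm_a = cluster.count_a / total_a * 1e6 if total_a else 0.0
        tpm_b = cluster.count_b / total_b * 1e6 if total_b else 0.0
        mfe_pass = fold.mfe < mfe_threshold
        if require_both_samples:
            expression_pass = tpm_a >= min_tpm and tpm_b >= min_tpm
        else:
            expression_pass = tpm_a >= min_tpm or tpm_b >= min_tpm
        verdict = bool(shape and mfe_pass and dicer_pass and expression_pass)
        rows.append(
            {
                "chrom": cluster.chrom,
                "strand": cluster.strand,
                "cluster_start": cluster.start,
                "cluster_end": cluster.end,
                "window_start": window.genomic_start,
                "window_end": window.genomic_end,
                "arm_role": window.role,
                "precursor_seq": window.sequence,
                "structure": fold.structure,
                "mfe": fold.mfe,
                "count_a": cluster.count_a,
                "count_b": cluster.count_b,
                "tpm_a": tpm_a,
                "tpm_b": tpm_b,
                "dicer_fraction": dicer_frac,
                "hairpin_shape": bool(shape),
                "mfe_pass": bool(mfe_pass),
                "dicer_pass": bool(dicer_pass),
                "expression_pass": bool(expression_pass),
                "verdict": verdict,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "chrom", "strand", "cluster_start", "cluster_end", "window_start",
                "window_end", "arm_role", "precursor_seq", "structure", "mfe",
                "count_a", "count_b", "tpm_a", "tpm_b", "dicer_fraction",
                "hairpin_shape", "mfe_pass", "dicer_pass", "expression_pass",
                "verdict",
            ]
        )
        df["novel_id"] = pd.Series(dtype=str)
        df["called"] = pd.Series(dtype=bool)
        return df
    # deduplicate accepted candidates whose windows overlap (one per hairpin)
    df["total"] = df["count_a"] + df["count_b"]
    df = df.sort_values(["total", "chrom", "cluster_start"], ascending=[False, True, True], ignore_index=True)
    kept: list[tuple[str, int, int]] = []
    novel_ids = []
    rank = 0
    for row in df.itertuples(index=False):
        if not row.verdict:
            novel_ids.append("")
            continue
        overlaps = any(
            c == row.chrom and row.window_start < e and s < row.window_end
            for c, s, e in kept
        )
        if overlaps:
            novel_ids.append("")
            continue
        kept.append((row.chrom, row.window_start, row.window_end))
        rank += 1
        novel_ids.append(f"novel-miR-{rank}")
    df["novel_id"] = novel_ids
    df["called"] = df["novel_id"] != ""
    return df.drop(columns=["total"])
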