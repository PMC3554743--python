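"""Consensus miRNA target prediction and term enrichment.

Four in-house seed-match parameterizations stand in for independent
prediction tools so the >=3-of-4 consensus rule is testable offline:

* M1 — 7mer-m8: perfect Watson-Crick complement of miRNA positions 2-8,
* M2 — 8mer: the 7mer-m8 site with an A opposite miRNA position 1,
* M3 — 7mer-A1 (positions 2-7 + A) OR 7mer-m8 with 3'-supplementary pairing
  (>= 4 contiguous complementary bases from miRNA positions 13-17 just
  upstream of the seed site),
* M4 — 7mer-m8 plus a seed-extended duplex energy below a threshold under
  the hairpin module's stacking model.

Externally produced per-tool gene lists can substitute for any method.
Enrichment of the retained targets uses the hypergeometric upper tail over a
user-supplied gene -> term map with Bonferroni correction across terms.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .fold import EnergyModel
from .io import revcomp

METHODS = ["M1", "M2", "M3", "M4"]
DUPLEX_ENERGY_THRESHOLD = -14.0  # kcal/mol


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _duplex_energy(mirna: str, utr: str, site: int, model: EnergyModel) -> float:
    """Stacking energy of the maximal contiguous duplex through the seed.

    miRNA position m (0-based) pairs UTR position ``site + 7 - m`` for the
    7mer-m8 register; complementarity is extended in both directions and the
    paired run scored with the nearest-neighbour stack table (kcal/mol).
    """
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def paired(m: int) -> bool:
        u = site + 7 - m
        return 0 <= u < len(utr) and 0 <= m < len(mirna) and utr[u] == comp.get(mirna[m], "?")

    lo = 1
    while paired(lo - 1):
        lo -= 1
    hi = 7
    while paired(hi + 1):
        hi += 1
    energy = 0.0
    rna = {"T": "U", "A": "A", "G": "G", "C": "C"}
    for m in range(lo, hi):
        pair1 = rna[mirna[m]] + rna[comp[mirna[m]]]
        pair2 = rna[mirna[m + 1]] + rna[comp[mirna[m + 1]]]
        energy += model.stack_energy(pair1, pair2) / 10.0
    return energy


def predict_targets_multimethod(
    mirna_id: str,
    mirna_seq: str,
    utrs: dict[str, str],
    energy_threshold: float = DUPLEX_ENERGY_THRESHOLD,
    model: EnergyModel | None = None,
) -> pd.DataFrame:
    """Scan every 3'UTR with the four methods for one mature miRNA.

    Returns one row per (gene, site) with the set of supporting methods; the
    per-gene support set used by the consensus filter is the union over
    sites.
    """
    model = model or EnergyModel.default()
    mirna = mirna_seq.upper().replace("U", "T")
    if len(mirna) < 19:
        raise ValueError("mature miRNA must be at least 19 nt")
    seed_m8 = revcomp(mirna[1:8])  # 7mer-m8 site, UTR 5'->3'
    seed_a1 = revcomp(mirna[1:7]) + "A"  # 7mer-A1 site
    supp_words = {
        revcomp(mirna[i : i + 4]) for i in range(12, min(14, len(mirna) - 3))
    }
    rows = []
    for gene, utr in utrs.items():
        utr = utr.upper()
        if len(utr) < 7:
            continue
        sites: dict[int, dict] = {}
        for pos in _find_all(utr, seed_m8):
            methods = {"M1"}
            seed_type = "7mer-m8"
            if pos + 7 < len(utr) and utr[pos + 7] == "A":
                methods.add("M2")
                methods.add("M3")  # an 8mer contains the 7mer-A1 site
                seed_type = "8mer"
            else:
                upstream = utr[max(0, pos - 12) : pos]
                if any(w in upstream for w in supp_words):
                    methods.add("M3")
            energy = _duplex_energy(mirna, utr, pos, model)
            if energy <= energy_threshold:
                methods.add("M4")
            sites[pos] = {"methods": methods, "seed_type": seed_type, "energy": energy}
        for pos in _find_all(utr, seed_a1):
            if pos in sites:
                continue
            sites[pos] = {
                "methods": {"M3"},
                "seed_type": "7mer-A1",
                "energy": float("nan"),
            }
        for pos, info in sorted(sites.items()):
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "gene_id": gene,
                    "site_position": pos,
                    "seed_type": info["seed_type"],
                    "duplex_energy": info["energy"],
                    "methods": ",".join(sorted(info["methods"])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "site_position", "seed_type",
                 "duplex_energy", "methods"],
    )


def predict_targets_table(
    mirnas: dict[str, str], utrs: dict[str, str], **kwargs
) -> pd.DataFrame:
    frames = [
        predict_targets_multimethod(mid, seq, utrs, **kwargs)
        for mid, seq in mirnas.items()
    ]
    if not frames:
        return predict_targets_multimethod("", "A" * 19, {})
    return pd.concat(frames, ignore_index=True)


def consensus_filter(predictions: pd.DataFrame, min_support: int = 3) -> pd.DataFrame:
    """Per (miRNA, gene) union of supporting methods; keep >= min_support."""
    if predictions.empty:
        return pd.DataFrame(columns=["mirna_id", "gene_id", "methods", "n_methods"])
    grouped = (
        predictions.groupby(["mirna_id", "gene_id"])["methods"]
        .apply(lambda s: ",".join(sorted(set(",".join(s).split(",")))))
        .reset_index()
    )
    grouped["n_methods"] = grouped["methods"].str.split(",").str.len()
    kept = grouped[grouped["n_methods"] >= min_support].reset_index(drop=True)
    return kept


def external_support_table(gene_lists: dict[str, list[str]], mirna_id: str) -> pd.DataFrame:
    """Build the prediction table from externally produced per-tool gene lists."""
    rows = []
    for method, genes in gene_lists.items():
        for gene in genes:
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "gene_id": gene,
                    "site_position": -1,
                    "seed_type": "external",
                    "duplex_energy": float("nan"),
                    "methods": method,
                }
            )
    return pd.DataFrame(rows)


def enrich(
    target_genes,
    gene_terms: pd.DataFrame,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail term enrichment with Bonferroni correction.

    For each term: the probability of >= k of the n target genes annotated
    to a term of K genes in a universe of N.  ``percentage`` is gene_count
    over the number of target genes carrying at least one annotation.
    Rows are sorted by raw p; ``significant`` flags bonferroni < alpha.
    """
    universe = sorted(set(universe))
    targets = sorted(set(target_genes) & set(universe))
    gt = gene_terms[gene_terms["gene"].isin(universe)]
    if not targets:
        return pd.DataFrame(
            columns=["term", "gene_count", "percentage", "p_raw", "bonferroni",
                     "significant"]
        )
    n_annotated_targets = gt[gt["gene"].isin(targets)]["gene"].nunique()
    N, n = len(universe), len(targets)
    term_genes = gt.groupby("term")["gene"].apply(set)
    n_terms = len(term_genes)
    rows = []
    for term, genes in term_genes.items():
        K = len(genes)
        k = len(genes & set(targets))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "gene_count": k,
                "percentage": k / n_annotated_targets if n_annotated_targets else 0.0,
                "p_raw": p,
                "bonferroni": min(1.0, p * n_terms),
            }
        )
    out = pd.DataFrame(rows).sort_values(["p_raw", "term"], ignore_index=True)
    out["significant"] = out["bonferroni"] < alpha
    return out
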