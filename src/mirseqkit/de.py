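"""Two-library differential expression of miRNA counts.

Counts are normalized to TPM (transcripts per million clean tags).  Each
miRNA is tested with an exact conditional binomial test: under the null of
equal relative abundance, given n = count_A + count_B, count_B follows
Binomial(n, q) with q = total_B / (total_A + total_B); the two-sided p-value
sums the probabilities of all outcomes no more likely than the observed one
(minimum-likelihood convention).  P-values are adjusted by the
Benjamini-Hochberg step-up procedure, and a miRNA is called Up/Down when the
adjusted p is below alpha AND the TPM fold change (library B over library A,
the resistant line over the parent) is at least ``min_fold``.  Zero TPMs are
floored (default 0.01) before the ratio so library-specific miRNAs get a
large finite log2 fold change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
MIN_FOLD = 2.0
TPM_FLOOR = 0.01

#: relative slack when comparing outcome likelihoods (float-tie protection)
_TIE_GAMMA = 1e-7


def tpm(count: float, library_total: float) -> float:
    """Transcripts per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count / library_total * 1e6


def two_library_test(
    count_a: int, count_b: int, total_a: int, total_b: int
) -> float:
    """Exact two-sided conditional binomial p-value for one miRNA."""
    return float(
        two_library_test_array(
            np.array([count_a]), np.array([count_b]), total_a, total_b
        )[0]
    )


def two_library_test_array(
    counts_a: np.ndarray, counts_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    """Vectorized exact test over many miRNAs (same library totals)."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    counts_a = np.asarray(counts_a, dtype=np.int64)
    counts_b = np.asarray(counts_b, dtype=np.int64)
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise ValueError("counts must be non-negative")
    n = counts_a + counts_b
    if np.any(n == 0):
        raise ValueError("a miRNA with zero counts in both libraries is untestable")
    q = total_b / (total_a + total_b)
    out = np.empty(len(n), dtype=float)
    for idx in range(len(n)):
        k = np.arange(n[idx] + 1)
        pmf = stats.binom.pmf(k, n[idx], q)
        p_obs = pmf[counts_b[idx]]
        out[idx] = min(1.0, float(pmf[pmf <= p_obs * (1 + _TIE_GAMMA)].sum()))
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def log2_fold_change(
    tpm_a: float, tpm_b: float, floor: float = TPM_FLOOR
) -> float:
    """log2(TPM_B / TPM_A) with the floor applied to zero sides only."""
    a = tpm_a if tpm_a > 0 else floor
    b = tpm_b if tpm_b > 0 else floor
    return float(np.log2(b / a))


def call_de(
    log2_fc: float, p_adj: float, alpha: float = ALPHA, min_fold: float = MIN_FOLD
) -> str:
    """Up/Down/NS call from adjusted p and fold change."""
    thresh = np.log2(min_fold)
    if p_adj < alpha and log2_fc >= thresh:
        return "Up"
    if p_adj < alpha and log2_fc <= -thresh:
        return "Down"
    return "NS"


def de_table(
    counts: pd.DataFrame,
    total_a: int,
    total_b: int,
    alpha: float = ALPHA,
    min_fold: float = MIN_FOLD,
    floor_tpm: float = TPM_FLOOR,
    id_column: str = "mirna_id",
) -> tuple[pd.DataFrame, dict]:
    """Test every miRNA detected in at least one library.

    ``counts`` needs columns ``mirna_id``/``count_a``/``count_b``.  Returns
    the ranked DE table (|log2FC| descending within direction) and a summary
    with tested/shared/up/down and >16-fold counts.
    """
    df = counts[[id_column, "count_a", "count_b"]].copy()
    df = df[(df["count_a"] + df["count_b"]) > 0].reset_index(drop=True)
    if df.empty:
        empty = pd.DataFrame(
            columns=[id_column, "count_a", "count_b", "tpm_a", "tpm_b",
                     "log2_fc", "p_raw", "p_adj", "call"]
        )
        return empty, {
            "n_tested": 0, "n_shared": 0, "n_up": 0, "n_down": 0,
            "n_over_16fold_up": 0, "n_over_16fold_down": 0,
        }
    df["tpm_a"] = df["count_a"] / total_a * 1e6
    df["tpm_b"] = df["count_b"] / total_b * 1e6
    df["log2_fc"] = [
        log2_fold_change(a, b, floor_tpm) for a, b in zip(df["tpm_a"], df["tpm_b"])
    ]
    df["p_raw"] = two_library_test_array(
        df["count_a"].to_numpy(), df["count_b"].to_numpy(), total_a, total_b
    )
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["call"] = [
        call_de(fc, p, alpha, min_fold) for fc, p in zip(df["log2_fc"], df["p_adj"])
    ]
    direction_rank = df["call"].map({"Up": 0, "Down": 1, "NS": 2})
    df = (
        df.assign(_rank=direction_rank, _mag=df["log2_fc"].abs())
        .sort_values(["_rank", "_mag", id_column], ascending=[True, False, True])
        .drop(columns=["_rank", "_mag"])
        .reset_index(drop=True)
    )
    summary = {
        "n_tested": int(len(df)),
        "n_shared": int(((df["count_a"] > 0) & (df["count_b"] > 0)).sum()),
        "n_up": int((df["call"] == "Up").sum()),
        "n_down": int((df["call"] == "Down").sum()),
        "n_over_16fold_up": int(((df["call"] == "Up") & (df["log2_fc"] > 4)).sum()),
        "n_over_16fold_down": int(((df["call"] == "Down") & (df["log2_fc"] < -4)).sum()),
    }
    return df, summary
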