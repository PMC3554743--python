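"""Exact test, BH adjustment, fold-change calls and the DE table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirseqkit.de import (
    bh_adjust,
    call_de,
    de_table,
    log2_fold_change,
    tpm,
    two_library_test,
    two_library_test_array,
)
from mirseqkit.simulate import simulate_two_library_counts

from helpers import bh_definitional, exact_two_sided_binomial


def test_tpm_arithmetic():
    assert tpm(0, 1_000_000) == 0.0
    assert tpm(1, 1_000_000) == 1.0
    assert tpm(57, 250_000) == pytest.approx(228.0)
    with pytest.raises(ValueError):
        tpm(1, 0)


def test_exact_test_known_values():
    assert two_library_test(5, 5, 10**6, 10**6) == pytest.approx(1.0)
    # all 20 counts on one side with equal totals: both extreme outcomes
    assert two_library_test(0, 20, 10**6, 10**6) == pytest.approx(2 * 0.5**20)
    assert two_library_test(20, 0, 10**6, 10**6) == pytest.approx(2 * 0.5**20)


def test_exact_test_matches_rational_oracle():
    rng = np.random.default_rng(21)
    for _ in range(60):
        a, b = int(rng.integers(0, 100)), int(rng.integers(0, 100))
        if a + b == 0:
            continue
        ta, tb = int(rng.integers(10**3, 10**6)), int(rng.integers(10**3, 10**6))
        got = two_library_test(a, b, ta, tb)
        want = exact_two_sided_binomial(a, b, ta, tb)
        assert got == pytest.approx(want, rel=1e-9), (a, b, ta, tb)


def test_exact_test_matches_scipy_binomtest():
    rng = np.random.default_rng(22)
    for _ in range(30):
        a, b = int(rng.integers(0, 60)), int(rng.integers(1, 60))
        ta, tb = 500_000, 700_000
        ref = stats.binomtest(b, a + b, tb / (ta + tb)).pvalue
        assert two_library_test(a, b, ta, tb) == pytest.approx(ref, rel=1e-6)


def test_exact_test_is_symmetric():
    rng = np.random.default_rng(23)
    for _ in range(30):
        a, b = int(rng.integers(0, 80)), int(rng.integers(1, 80))
        ta, tb = int(rng.integers(10**4, 10**6)), int(rng.integers(10**4, 10**6))
        assert two_library_test(a, b, ta, tb) == pytest.approx(
            two_library_test(b, a, tb, ta), rel=1e-9
        )


def test_exact_test_input_validation():
    with pytest.raises(ValueError):
        two_library_test(0, 0, 10**6, 10**6)
    with pytest.raises(ValueError):
        two_library_test(1, 1, 0, 10**6)
    with pytest.raises(ValueError):
        two_library_test_array(np.array([-1]), np.array([1]), 10, 10)


def test_bh_known_values():
    assert bh_adjust([0.05]).tolist() == [0.05]
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_adjust([]).size == 0
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_bh_matches_definitional_oracle():
    rng = np.random.default_rng(31)
    for _ in range(50):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        assert np.allclose(bh_adjust(p), bh_definitional(p.tolist()), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(32)
    p = rng.uniform(size=200)
    _, ref, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(bh_adjust(p), ref)


def test_bh_preserves_p_value_order():
    rng = np.random.default_rng(33)
    p = rng.uniform(size=100)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
    assert (adj >= p).all() and (adj <= 1.0).all()


def test_fold_change_floor_applies_to_zero_sides_only():
    assert log2_fold_change(4.0, 8.0) == pytest.approx(1.0)
    assert log2_fold_change(0.0, 50.0) == pytest.approx(np.log2(50 / 0.01))
    assert log2_fold_change(50.0, 0.0) == pytest.approx(-np.log2(50 / 0.01))
    # a nonzero value below the floor is not floored
    assert log2_fold_change(0.005, 0.005) == pytest.approx(0.0)


def test_calls_on_published_style_rows():
    assert call_de(9.04, 1.56e-23) == "Up"
    assert call_de(-11.63, 4.47e-133) == "Down"
    assert call_de(0.9, 1e-10) == "NS"  # significant p but under 2-fold
    assert call_de(3.0, 0.2) == "NS"
    assert call_de(1.0, 0.049) == "Up"  # both boundaries: fold inclusive, p strict
    assert call_de(1.0, 0.05) == "NS"


def test_de_table_contract():
    counts = pd.DataFrame(
        {
            "mirna_id": ["m1", "m2", "m3", "m4"],
            "count_a": [1000, 10, 0, 0],
            "count_b": [10, 1000, 40, 0],
        }
    )
    table, summary = de_table(counts, 100_000, 100_000)
    assert summary["n_tested"] == 3  # the all-zero row is dropped
    assert summary["n_shared"] == 2
    got = table.set_index("mirna_id")
    assert got.loc["m1", "call"] == "Down" and got.loc["m2", "call"] == "Up"
    assert got.loc["m3", "call"] == "Up"  # library-specific, floored ratio
    assert summary["n_over_16fold_up"] == 2 and summary["n_over_16fold_down"] == 1
    # recompute every column from the primitives
    for r in table.itertuples(index=False):
        assert r.p_raw == pytest.approx(
            two_library_test(r.count_a, r.count_b, 100_000, 100_000)
        )
        assert r.call == call_de(r.log2_fc, r.p_adj)
    assert np.allclose(
        np.sort(table["p_adj"]), np.sort(bh_adjust(table["p_raw"].to_numpy()))
    )


def test_de_table_empty_input():
    counts = pd.DataFrame({"mirna_id": [], "count_a": [], "count_b": []})
    table, summary = de_table(counts, 1_000, 1_000)
    assert table.empty and summary["n_tested"] == 0


def test_de_stage_recovers_planted_directions(run_dir):
    table = pd.read_csv(run_dir / "de_known.tsv", sep="\t").set_index("mirna_id")
    for arm in ("5p", "3p"):
        assert table.loc[f"mir-1-{arm}", "call"] == "Up"
        assert table.loc[f"mir-2-{arm}", "call"] == "Down"
    nulls = [i for i in table.index if not i.startswith(("mir-1-", "mir-2-"))]
    assert (table.loc[nulls, "call"] == "NS").all()
    novel = pd.read_csv(run_dir / "de_novel.tsv", sep="\t")
    assert (novel["call"] == "Up").sum() == 1  # the planted hidden-1 shift


def test_parameter_recovery_quick():
    rng = np.random.default_rng(55)
    true_fc = np.array([3.0, -3.0, 2.0, -2.0])
    tpm_a = np.full(24, 2_000.0)
    fc = np.concatenate([true_fc, np.zeros(20)])
    ok = 0
    for _ in range(10):
        a, b = simulate_two_library_counts(tpm_a, fc, (100_000, 100_000), rng)
        p = two_library_test_array(a, b, 100_000, 100_000)
        adj = bh_adjust(p)
        lfc = np.array(
            [log2_fold_change(x / 0.1, y / 0.1) for x, y in zip(a, b)]
        )
        calls = [call_de(l, q) for l, q in zip(lfc, adj)]
        want = ["Up", "Down", "Up", "Down"]
        ok += calls[:4] == want
    assert ok >= 9
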