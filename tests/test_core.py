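"""Unit and property tests for the two-stage testing engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stagewise.core import (
    ValidationError,
    bh_adjust,
    compute_alpha_II,
    confirm,
    gene_level_fdp,
    msrb_adjust,
    screen,
    shaffer_t_sequence,
)
from conftest import holm_adjust_reference

pvec = st.lists(
    st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=12
)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.5], [0.5]),
        ([0.01, 0.04, 0.03, 0.005], [0.02, 0.04, 0.04, 0.02]),
        ([0.2] * 5, [0.2] * 5),
    ],
)
def test_bh_adjust_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected)


@settings(deadline=None, derandomize=True)
@given(pvec)
def test_bh_adjust_matches_statsmodels(p):
    from statsmodels.stats.multitest import multipletests

    _, ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


@pytest.mark.parametrize("bad", [[], [1.2], [-0.1], [np.nan]])
def test_bh_adjust_rejects_invalid(bad):
    with pytest.raises(ValidationError):
        bh_adjust(bad)


# ---------------------------------------------------------------------------
# Screening and the confirmation level
# ---------------------------------------------------------------------------

def test_screen_single_gene():
    res = screen(pd.DataFrame({"gene": ["g"], "pvalue": [0.04]}), alpha_I=0.05)
    assert res.R == 1 and res.G == 1
    assert res.alpha_II == pytest.approx(0.05)


def test_screen_all_null_pvalues_of_one():
    res = screen(pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"]), alpha_I=0.05)
    assert res.R == 0 and res.alpha_II == 0.0
    assert not res.table["rejected"].any()


def test_screen_duplicate_genes_rejected():
    with pytest.raises(ValidationError):
        screen(pd.DataFrame({"gene": ["a", "a"], "pvalue": [0.1, 0.2]}))


def test_screen_level_bounded_under_global_null(rng):
    """BH at level alpha rejects anything in at most ~alpha of null datasets."""
    reps, G, alpha = 4000, 100, 0.05
    p = np.sort(rng.uniform(size=(reps, G)), axis=1)
    any_rejection = (p * G / np.arange(1, G + 1) <= alpha).any(axis=1)
    rate = any_rejection.mean()
    se = np.sqrt(alpha * (1 - alpha) / reps)
    assert rate <= alpha + 3 * se


@pytest.mark.parametrize(
    "R, G, alpha, expected",
    [(100, 100, 0.05, 0.05), (0, 1000, 0.05, 0.0), (40, 100, 0.05, 0.02)],
)
def test_compute_alpha_II(R, G, alpha, expected):
    assert compute_alpha_II(R, G, alpha) == pytest.approx(expected)


def test_compute_alpha_II_rejects_R_above_G():
    with pytest.raises(ValidationError):
        compute_alpha_II(5, 4, 0.05)


# ---------------------------------------------------------------------------
# Shaffer t-sequences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n, context, expected",
    [
        (5, "dtu", [3, 3, 3, 2, 1]),
        (2, "dtu", [0, 0]),
        (4, "dte", [3, 3, 2, 1]),
        (1, "dte", [0]),
        (3, "holm", [3, 2, 1]),
        (3, "dge_2x2", [1, 1, 1]),
        (4, "dge_2x2_avg", [1, 1, 1, 1]),
        (4, "screened_free", [3, 3, 2, 1]),
    ],
)
def test_shaffer_t_sequence(n, context, expected):
    np.testing.assert_array_equal(shaffer_t_sequence(n, context), expected)


@pytest.mark.parametrize(
    "n, context", [(4, "dge_2x2"), (3, "dge_2x2_avg"), (1, "dtu"), (3, "bogus")]
)
def test_shaffer_t_sequence_invalid(n, context):
    with pytest.raises(ValidationError):
        shaffer_t_sequence(n, context)


@pytest.mark.parametrize("context", ["dte", "dtu", "screened_free", "holm"])
@pytest.mark.parametrize("n", range(1, 9))
def test_t_sequence_never_exceeds_holm(context, n):
    if context == "dtu" and n == 1:
        pytest.skip("a DTU gene needs two transcripts")
    t = shaffer_t_sequence(n, context)
    assert (t <= np.arange(n, 0, -1)).all()


# ---------------------------------------------------------------------------
# MSRB adjustment
# ---------------------------------------------------------------------------

def test_msrb_unit_t_leaves_pvalues_unchanged():
    """t = (1,1,1): no additional within-gene correction (2x2 DGE design)."""
    np.testing.assert_allclose(
        msrb_adjust([0.01, 0.02, 0.3], [1, 1, 1]), [0.01, 0.02, 0.3]
    )


def test_msrb_zero_t_auto_rejects():
    """Two-transcript DTU genes are auto-confirmed once screened."""
    np.testing.assert_allclose(msrb_adjust([0.9, 0.8], [0, 0]), [0.0, 0.0])


def test_msrb_length_mismatch():
    with pytest.raises(ValidationError):
        msrb_adjust([0.1, 0.2], [1])


@settings(deadline=None, derandomize=True)
@given(pvec)
def test_msrb_with_holm_sequence_equals_holm(p):
    t = np.arange(len(p), 0, -1)
    np.testing.assert_allclose(
        msrb_adjust(p, t), holm_adjust_reference(p), atol=1e-12
    )


@settings(deadline=None, derandomize=True)
@given(
    pvec,
    st.floats(0.001, 0.2),
    st.randoms(use_true_random=False),
)
def test_msrb_rejections_superset_of_holm(p, alpha, rand):
    """Any valid t(j) <= n-j+1 is at least as powerful as Holm."""
    n = len(p)
    t = np.array([rand.randint(0, n - j) for j in range(n)])
    msrb_rej = msrb_adjust(p, t) <= alpha
    holm_rej = holm_adjust_reference(p) <= alpha
    assert (msrb_rej | ~holm_rej).all()


# ---------------------------------------------------------------------------
# Confirmation stage
# ---------------------------------------------------------------------------

def test_confirm_worked_three_gene_case(three_gene_case):
    """Hand-computed trace: R=2, alpha_II=1/30, Holm within genes."""
    screening_p, hyp = three_gene_case
    scr = screen(screening_p, alpha_I=0.05)
    assert scr.R == 2
    assert scr.alpha_II == pytest.approx(1 / 30)
    res = confirm(hyp, scr, context="holm")
    tab = res.table.set_index(["gene", "hypothesis"])
    # gene A: sorted (0.01, 0.04) * (2, 1) -> within (0.02, 0.04)
    assert tab.loc[("A", "h1"), "p_within"] == pytest.approx(0.02)
    assert tab.loc[("A", "h2"), "p_within"] == pytest.approx(0.04)
    assert bool(tab.loc[("A", "h1"), "rejected"]) is True  # 0.02 <= 1/30
    assert bool(tab.loc[("A", "h2"), "rejected"]) is False
    # gene B: (0.5, 0.6) * (2, 1) -> (1.0, cummax 1.0)
    assert tab.loc[("B", "h1"), "p_within"] == pytest.approx(1.0)
    assert tab.loc[("B", "h2"), "p_within"] == pytest.approx(1.0)
    assert not tab.loc["B", "rejected"].any()
    # gene C failed screening: untouched regardless of tiny p-values
    assert not tab.loc[("C", "h1"), "rejected"]
    assert tab.loc[("C", "h1"), "p_stagewise"] == 1.0
    # stage-wise scale: within * G / R
    assert tab.loc[("A", "h1"), "p_stagewise"] == pytest.approx(0.03)


def test_confirm_unscreened_gene_is_an_error(three_gene_case):
    screening_p, hyp = three_gene_case
    scr = screen(screening_p, alpha_I=0.05)
    bad = pd.concat(
        [hyp, pd.DataFrame({"gene": ["Z"], "hypothesis": ["h1"], "pvalue": [0.01]})]
    )
    with pytest.raises(ValidationError):
        confirm(bad, scr)


def test_confirm_zero_screening_rejections_is_valid():
    scr = screen(pd.Series({"a": 0.9, "b": 0.8}), alpha_I=0.05)
    hyp = pd.DataFrame(
        {"gene": ["a", "b"], "hypothesis": ["h", "h"], "pvalue": [0.001, 0.001]}
    )
    res = confirm(hyp, scr)
    assert not res.table["rejected"].any()
    assert (res.table["p_stagewise"] == 1.0).all()


def test_confirm_full_screening_pass_equals_fwer_at_alpha_I(rng):
    """With R = G, alpha_II = alpha_I and decisions match a plain Holm test."""
    genes = [f"g{i}" for i in range(20)]
    scr = screen(pd.Series(1e-9, index=genes), alpha_I=0.05)
    assert scr.R == scr.G
    hyp = pd.DataFrame(
        {
            "gene": np.repeat(genes, 3),
            "hypothesis": np.tile(["a", "b", "c"], 20),
            "pvalue": rng.uniform(size=60) ** 2,
        }
    )
    res = confirm(hyp, scr, context="holm")
    for g, sub in hyp.groupby("gene"):
        ref = holm_adjust_reference(sub["pvalue"].to_numpy()) <= 0.05
        got = res.table.set_index(["gene", "hypothesis"]).loc[g, "rejected"]
        np.testing.assert_array_equal(
            got.loc[sub["hypothesis"]].to_numpy(), ref
        )


def test_confirm_round_trip_identity(rng):
    """p_stagewise <= alpha_I reproduces the two-stage threshold decisions."""
    for _ in range(5):
        G = 50
        genes = [f"g{i}" for i in range(G)]
        scr = screen(pd.Series(rng.uniform(size=G) ** 3, index=genes), alpha_I=0.05)
        hyp = pd.DataFrame(
            {
                "gene": np.repeat(genes, 4),
                "hypothesis": np.tile(["a", "b", "c", "d"], G),
                "pvalue": rng.uniform(size=4 * G) ** 2,
            }
        )
        res = confirm(hyp, scr, context="screened_free")
        via_threshold = res.table["p_within"] <= scr.alpha_II
        via_threshold &= res.table["passed_screening"]
        via_stagewise = (res.table["p_stagewise"] <= scr.alpha_I) & res.table[
            "passed_screening"
        ]
        np.testing.assert_array_equal(
            res.table["rejected"].to_numpy(), via_threshold.to_numpy()
        )
        np.testing.assert_array_equal(
            res.table["rejected"].to_numpy(), via_stagewise.to_numpy()
        )


def test_confirm_adjusted_p_monotone_within_gene(rng):
    genes = [f"g{i}" for i in range(30)]
    scr = screen(pd.Series(rng.uniform(size=30) ** 4, index=genes), alpha_I=0.1)
    hyp = pd.DataFrame(
        {
            "gene": np.repeat(genes, 5),
            "hypothesis": np.tile(list("abcde"), 30),
            "pvalue": rng.uniform(size=150),
        }
    )
    res = confirm(hyp, scr, context="holm")
    merged = res.table.sort_values(["gene", "pvalue"])
    for _, sub in merged.groupby("gene"):
        assert (np.diff(sub["p_within"].to_numpy()) >= -1e-15).all()


def test_confirm_dropped_na_pvalues_shrink_the_family():
    """A missing p-value must not inflate the within-gene correction."""
    scr = screen(pd.Series({"g": 0.001}), alpha_I=0.05)
    hyp = pd.DataFrame(
        {
            "gene": ["g", "g", "g"],
            "hypothesis": ["a", "b", "c"],
            "pvalue": [0.02, np.nan, 0.5],
        }
    )
    res = confirm(hyp, scr, context="holm")
    assert len(res.table) == 2
    # n_g = 2 after dropping: holm t = (2, 1), so p_within for 'a' is 0.04
    tab = res.table.set_index("hypothesis")
    assert tab.loc["a", "p_within"] == pytest.approx(0.04)


# ---------------------------------------------------------------------------
# Gene-level FDP
# ---------------------------------------------------------------------------

def _fdp_oracle(result, truth):
    """Exhaustive per-gene classification, independent of the package path."""
    discovered = list(result.screening.rejected_genes)
    if not discovered:
        return 0.0
    t = truth.set_index(["gene", "hypothesis"])["is_null"]
    false_genes = 0
    for g in discovered:
        rows = result.table[result.table["gene"] == g]
        nulls = [bool(t.loc[(g, h)]) for h in rows["hypothesis"]]
        fully_null = all(nulls)
        any_false = any(
            n and r for n, r in zip(nulls, rows["rejected"].tolist())
        )
        false_genes += fully_null or any_false
    return false_genes / len(discovered)


def test_gene_level_fdp_no_rejections():
    scr = screen(pd.Series({"a": 0.9}), alpha_I=0.05)
    hyp = pd.DataFrame({"gene": ["a"], "hypothesis": ["h"], "pvalue": [0.5]})
    res = confirm(hyp, scr)
    truth = hyp.assign(is_null=True)[["gene", "hypothesis", "is_null"]]
    assert gene_level_fdp(res, truth) == 0.0


def test_gene_level_fdp_all_null_rejected_is_one():
    scr = screen(pd.Series({"a": 1e-6, "b": 1e-6}), alpha_I=0.05)
    hyp = pd.DataFrame(
        {"gene": ["a", "b"], "hypothesis": ["h", "h"], "pvalue": [0.9, 0.9]}
    )
    res = confirm(hyp, scr)
    truth = hyp.assign(is_null=True)[["gene", "hypothesis", "is_null"]]
    assert gene_level_fdp(res, truth) == 1.0


def test_gene_level_fdp_matches_oracle(rng):
    G = 40
    genes = [f"g{i}" for i in range(G)]
    scr = screen(pd.Series(rng.uniform(size=G) ** 3, index=genes), alpha_I=0.1)
    hyp = pd.DataFrame(
        {
            "gene": np.repeat(genes, 3),
            "hypothesis": np.tile(["a", "b", "c"], G),
            "pvalue": rng.uniform(size=3 * G) ** 2,
        }
    )
    res = confirm(hyp, scr, context="holm")
    truth = hyp[["gene", "hypothesis"]].assign(is_null=rng.uniform(size=3 * G) < 0.5)
    assert gene_level_fdp(res, truth) == pytest.approx(_fdp_oracle(res, truth))


def test_gene_level_fdp_missing_truth_is_error(three_gene_case):
    screening_p, hyp = three_gene_case
    scr = screen(screening_p, alpha_I=0.05)
    res = confirm(hyp, scr)
    truth = hyp.iloc[:3][["gene", "hypothesis"]].assign(is_null=True)
    with pytest.raises(ValidationError):
        gene_level_fdp(res, truth)
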