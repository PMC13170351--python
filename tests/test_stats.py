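"""Statistics against closed-form and summation oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from editscan._util import rng_for
from editscan.stats import (
    anova2_balanced,
    arg2_codon_enrichment,
    bh_fdr,
    count_codons,
    group_test,
    sidak_adjust,
    tpm,
    zscore_rows,
)


# ---------------------------------------------------------------------------
# z-score


def test_zscore_row_hand_arithmetic():
    m = pd.DataFrame([[10.0, 20.0, 30.0]], index=["s1"], columns=list("abc"))
    z, flagged = zscore_rows(m)
    assert flagged == []
    assert np.allclose(z.loc["s1"], [-1.0, 0.0, 1.0])  # sample sd = 10


def test_zscore_constant_row_flagged_as_zeros():
    m = pd.DataFrame([[5.0, 5.0, 5.0]], index=["s1"])
    z, flagged = zscore_rows(m)
    assert flagged == ["s1"]
    assert np.allclose(z.loc["s1"], 0.0)


def test_zscore_rows_standardized_and_missing_preserved():
    rng = rng_for(51, "z")
    m = pd.DataFrame(rng.random((6, 5)) * 100)
    m.iloc[0, 2] = np.nan
    z, _ = zscore_rows(m)
    assert np.isnan(z.iloc[0, 2])
    for _, row in z.iterrows():
        obs = row.dropna()
        assert obs.mean() == pytest.approx(0.0, abs=1e-12)
        assert obs.std(ddof=1) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# group tests


def test_student_t_matches_textbook_closed_form():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
    res = group_test({"A": a, "B": b}, method="student_t")
    # pooled sd = 1, se = sqrt(2/3)
    t_expect = (a.mean() - b.mean()) / np.sqrt(2.0 / 3.0)
    p_expect = 2 * sps.t.sf(abs(t_expect), df=4)
    assert res.statistic == pytest.approx(t_expect)
    assert res.pvalue == pytest.approx(p_expect)
    assert res.group_means == {"A": 2.0, "B": 5.0}


def test_identical_groups_give_zero_statistic_p_one():
    g = np.array([3.0, 4.0, 5.0])
    for method in ("student_t", "welch_t"):
        res = group_test({"A": g, "B": g.copy()}, method=method)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)


def test_welch_differs_from_student_under_unequal_variance():
    rng = rng_for(52, "welch")
    a = rng.normal(0, 1, 10)
    b = rng.normal(0, 8, 4)
    rs = group_test({"A": a, "B": b}, method="student_t")
    rw = group_test({"A": a, "B": b}, method="welch_t")
    assert rs.pvalue != pytest.approx(rw.pvalue)


def test_anova1_with_tukey_posthoc():
    rng = rng_for(53, "anova")
    groups = {
        "a": rng.normal(0, 1, 6),
        "b": rng.normal(0, 1, 6),
        "c": rng.normal(3, 1, 6),
    }
    res = group_test(groups, method="anova1", tukey=True)
    f_expect, p_expect = sps.f_oneway(*groups.values())
    assert res.statistic == pytest.approx(float(f_expect))
    assert res.pvalue == pytest.approx(float(p_expect))
    assert res.extra["tukey"][("a", "c")] < 0.01
    assert res.extra["tukey"][("a", "b")] > 0.05


def test_anova2_balanced_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = rng_for(54, "anova2")
    groups = {}
    rows = []
    for a in ("wt", "mut"):
        for b in ("log", "stat"):
            vals = rng.normal(1.0 + (a == "mut") * 2 + (b == "stat"), 1.0, 4)
            groups[(a, b)] = vals
            rows += [{"a": a, "b": b, "y": v} for v in vals]
    table = anova2_balanced(groups)
    df = pd.DataFrame(rows)
    fit = ols("y ~ C(a) * C(b)", data=df).fit()
    smtab = sm.stats.anova_lm(fit, typ=2)
    assert table.loc["factor_a", "F"] == pytest.approx(smtab.loc["C(a)", "F"])
    assert table.loc["factor_b", "p"] == pytest.approx(smtab.loc["C(b)", "PR(>F)"])
    assert table.loc["interaction", "F"] == pytest.approx(
        smtab.loc["C(a):C(b)", "F"]
    )


def test_anova2_rejects_unbalanced_or_incomplete_layouts():
    rng = rng_for(55, "anova2bad")
    complete = {
        (a, b): rng.normal(size=3) for a in "xy" for b in "uv"
    }
    bad = dict(complete)
    bad[("x", "u")] = rng.normal(size=5)
    with pytest.raises(ValueError, match="balanced"):
        anova2_balanced(bad)
    incomplete = {k: v for k, v in complete.items() if k != ("y", "v")}
    with pytest.raises(ValueError, match="complete"):
        anova2_balanced(incomplete)


# ---------------------------------------------------------------------------
# multiple testing


def test_bh_matches_step_up_formula():
    p = np.array([0.01, 0.02, 0.03, 0.04])
    adj = bh_fdr(p)
    m = 4
    expect = [p[i] * m / (i + 1) for i in range(m)]
    expect = np.minimum.accumulate(expect[::-1])[::-1]
    assert np.allclose(adj, expect)
    assert bh_fdr([0.2]) == pytest.approx([0.2])


def test_bh_matches_statsmodels_on_random_vectors():
    from statsmodels.stats.multitest import multipletests

    rng = rng_for(56, "bh")
    for _ in range(50):
        p = rng.random(int(rng.integers(1, 40)))
        ours = bh_fdr(p)
        _, theirs, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(ours, theirs)
        assert np.all(ours >= p - 1e-15)  # adjusted >= raw
        assert np.all(ours <= 1.0)
        # order preserving
        order = np.argsort(p)
        assert np.all(np.diff(ours[order]) >= -1e-15)


def test_sidak_single_and_multiple():
    assert sidak_adjust([0.05]) == pytest.approx([0.05])
    adj = sidak_adjust([0.01, 0.02, 0.03])
    assert np.allclose(adj, 1 - (1 - np.array([0.01, 0.02, 0.03])) ** 3)


# ---------------------------------------------------------------------------
# TPM


def test_tpm_examples_and_invariance():
    assert np.allclose(tpm([5, 5, 5, 5], [100, 100, 100, 100]), [250_000.0] * 4)
    got = tpm([10, 10], [100, 200])
    assert np.allclose(got, [2e6 / 3, 1e6 / 3])
    rng = rng_for(57, "tpm")
    c = rng.integers(1, 1000, 20)
    ln = rng.integers(100, 5000, 20)
    base = tpm(c, ln)
    assert base.sum() == pytest.approx(1e6)
    assert np.allclose(base, tpm(c * 7, ln))  # scaling counts is a no-op
    with pytest.raises(ValueError):
        tpm([0, 0], [100, 100])


# ---------------------------------------------------------------------------
# codon usage


def test_arg2_codon_membership():
    arg2, total = count_codons(["CGTCGACGC"])
    assert (arg2, total) == (3, 3)
    arg2, total = count_codons(["CGGAGGATG"])  # CGG is Arg but not Arg2-dependent
    assert (arg2, total) == (0, 3)


def test_out_of_frame_cds_is_an_error_listing_offenders():
    with pytest.raises(ValueError, match=r"\[1\]"):
        count_codons(["CGTCGA", "CGTC"])


def test_fisher_identical_rates_gives_or_one_p_one():
    a = ["CGT" * 5 + "AAA" * 95]
    b = ["CGA" * 5 + "GGG" * 95]
    res = arg2_codon_enrichment(a, b)
    assert res.statistic == pytest.approx(1.0)
    assert res.pvalue == pytest.approx(1.0)


def hypergeom_two_sided(table):
    """Exhaustive summation of tables with probability <= observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = sps.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = sps.hypergeom.pmf(k, n, col1, row1)
        if pk <= obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def test_fisher_matches_hypergeometric_summation():
    res = arg2_codon_enrichment(
        ["CGT" * 12 + "AAA" * 88], ["CGT" * 3 + "AAA" * 97]
    )
    expect = hypergeom_two_sided([[12, 88], [3, 97]])
    assert res.pvalue == pytest.approx(expect, abs=1e-10)


def test_fisher_p_invariant_under_transposition_and_swaps():
    t = np.array([[12, 88], [3, 97]])
    p0 = sps.fisher_exact(t)[1]
    for variant in (t.T, t[::-1], t[:, ::-1], t[::-1, ::-1].T):
        assert sps.fisher_exact(variant)[1] == pytest.approx(p0)
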