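"""Editing-matrix normalization, group comparisons, FDR control, TPM, and
codon-usage enrichment.

The editing matrix is sites x samples in percent; rows are z-scored for
heatmap display.  Group comparisons are the classical closed-form tests
(Student/Welch t, one-way ANOVA with optional Tukey HSD, balanced
two-way ANOVA), with Benjamini-Hochberg step-up control across sites and
Sidak adjustment for planned contrasts.  Expression is summarised as TPM
from strand-consistent counts.  The tRNA-Arg2 codon-usage question —
whether one gene set leans more on the CGU/CGA/CGC codons that the
wobble-edited tRNA decodes — is a 2x2 Fisher exact test on pooled codon
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ARG2_CODONS = ("CGU", "CGA", "CGC")  # decoded via the edited wobble position


@dataclass
class TestResult:
    test_id: str
    method: str
    statistic: float
    pvalue: float
    adjusted_pvalue: float | None = None
    group_means: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# matrix normalization


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-row (x - mean) / sd over non-missing entries; sample sd (ddof=1).

    Rows with fewer than two observed values or zero variance cannot be
    normalized: they are emitted as all-zero (observed positions) and
    returned in the flagged list.
    """
    out = matrix.astype(float).copy()
    flagged = []
    for idx, row in matrix.iterrows():
        vals = row.astype(float)
        obs = vals.dropna()
        sd = obs.std(ddof=1) if len(obs) >= 2 else 0.0
        if len(obs) < 2 or sd == 0 or not np.isfinite(sd):
            flagged.append(idx)
            out.loc[idx] = vals.where(vals.isna(), 0.0)
        else:
            out.loc[idx] = (vals - obs.mean()) / sd
    return out, flagged


# ---------------------------------------------------------------------------
# group tests


def group_test(
    values_by_group: dict[str, np.ndarray],
    method: str = "welch_t",
    tukey: bool = False,
    test_id: str = "",
) -> TestResult:
    """Compare groups of editing levels (or any measurements).

    Methods: ``student_t`` (pooled variance), ``welch_t`` (unequal
    variance), ``anova1`` (one-way F, optional Tukey HSD post hoc), and
    ``anova2_balanced`` (group keys must be (factor_a, factor_b) tuples
    forming a complete balanced layout; the reported statistic is the
    factor_a main effect, with the full table in ``extra``).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 observations")
    means = {str(k): float(np.mean(v)) for k, v in groups.items()}

    if method in ("student_t", "welch_t"):
        if len(groups) != 2:
            raise ValueError("t-tests compare exactly 2 groups")
        a, b = groups.values()
        stat, p = sps.ttest_ind(a, b, equal_var=(method == "student_t"))
        return TestResult(test_id, method, float(stat), float(p), group_means=means)

    if method == "anova1":
        stat, p = sps.f_oneway(*groups.values())
        extra = {}
        if tukey:
            hsd = sps.tukey_hsd(*groups.values())
            names = list(groups)
            extra["tukey"] = {
                (names[i], names[j]): float(hsd.pvalue[i, j])
                for i in range(len(names))
                for j in range(i + 1, len(names))
            }
        return TestResult(test_id, method, float(stat), float(p),
                          group_means=means, extra=extra)

    if method == "anova2_balanced":
        table = anova2_balanced(groups)
        row = table.loc["factor_a"]
        return TestResult(
            test_id, method, float(row["F"]), float(row["p"]),
            group_means=means, extra={"anova_table": table},
        )
    raise ValueError(f"unknown method {method!r}")


def anova2_balanced(groups: dict[tuple, np.ndarray]) -> pd.DataFrame:
    """Closed-form two-way ANOVA with interaction for a balanced layout.

    ``groups`` maps (level_a, level_b) cells to equal-sized replicate
    arrays covering the full cross.  Unbalanced or incomplete layouts are
    rejected — the sums-of-squares decomposition below is only exact for
    the balanced case.
    """
    keys = list(groups)
    if not all(isinstance(k, tuple) and len(k) == 2 for k in keys):
        raise ValueError("anova2 group keys must be (factor_a, factor_b) tuples")
    a_levels = sorted({k[0] for k in keys})
    b_levels = sorted({k[1] for k in keys})
    if set(keys) != {(a, b) for a in a_levels for b in b_levels}:
        raise ValueError("unsupported design: two-way layout must be complete")
    sizes = {len(np.asarray(v)) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("unsupported design: two-way layout must be balanced")
    r = sizes.pop()
    if r < 2:
        raise ValueError("need >= 2 replicates per cell for the interaction term")

    data = np.array(
        [[np.asarray(groups[(a, b)], dtype=float) for b in b_levels] for a in a_levels]
    )  # shape (A, B, r)
    A, B = len(a_levels), len(b_levels)
    grand = data.mean()
    mean_a = data.mean(axis=(1, 2))
    mean_b = data.mean(axis=(0, 2))
    mean_ab = data.mean(axis=2)

    ss_a = B * r * ((mean_a - grand) ** 2).sum()
    ss_b = A * r * ((mean_b - grand) ** 2).sum()
    ss_ab = r * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_err = ((data - mean_ab[:, :, None]) ** 2).sum()

    rows = {}
    df_err = A * B * (r - 1)
    ms_err = ss_err / df_err
    for name, ss, df in (
        ("factor_a", ss_a, A - 1),
        ("factor_b", ss_b, B - 1),
        ("interaction", ss_ab, (A - 1) * (B - 1)),
    ):
        ms = ss / df
        F = ms / ms_err
        rows[name] = {"ss": ss, "df": df, "F": F, "p": float(sps.f.sf(F, df, df_err))}
    rows["error"] = {"ss": ss_err, "df": df_err, "F": np.nan, "p": np.nan}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; preserves the
    input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def sidak_adjust(pvals) -> np.ndarray:
    """Sidak adjustment for k planned comparisons: 1 - (1 - p)^k."""
    p = np.asarray(pvals, dtype=float)
    return 1.0 - (1.0 - p) ** p.size


# ---------------------------------------------------------------------------
# expression


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from per-gene counts and lengths.

    rate_g = count_g / length_g; TPM_g = 1e6 * rate_g / sum(rate).  The
    upstream counting must already respect the reverse-stranded library
    (reads assigned to the transcript they are antisense to).
    """
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if np.any(ln <= 0):
        raise ValueError("lengths must be positive")
    rate = c / ln
    total = rate.sum()
    if total == 0:
        raise ValueError("zero total expression")
    return 1e6 * rate / total


# ---------------------------------------------------------------------------
# codon usage


def count_codons(cds_seqs: list[str]) -> tuple[int, int]:
    """(tRNA-Arg2-dependent codons, total codons) over a CDS set.

    Sequences may be DNA or RNA; each must be in frame (length divisible
    by 3).  Arg2-dependent codons are CGU, CGA, CGC — the three arginine
    codons decoded through the edited wobble position.
    """
    offenders = [i for i, s in enumerate(cds_seqs) if len(s) % 3 != 0]
    if offenders:
        raise ValueError(f"CDS length not divisible by 3 at indices {offenders}")
    arg2 = total = 0
    for s in cds_seqs:
        s = s.upper().replace("T", "U")
        for i in range(0, len(s), 3):
            total += 1
            if s[i : i + 3] in ARG2_CODONS:
                arg2 += 1
    return arg2, total


def arg2_codon_enrichment(
    cds_set_a: list[str], cds_set_b: list[str], test_id: str = "arg2_codon_usage"
) -> TestResult:
    """Two-sided Fisher exact test on Arg2-dependent codon frequency.

    Builds the 2x2 table [arg2-dependent vs other codons] x [set A vs
    set B] from pooled codon counts and reports the odds ratio and the
    exact two-sided p (tables with probability <= the observed one).
    """
    a_arg2, a_total = count_codons(cds_set_a)
    b_arg2, b_total = count_codons(cds_set_b)
    table = np.array(
        [[a_arg2, a_total - a_arg2], [b_arg2, b_total - b_arg2]], dtype=int
    )
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(
        test_id,
        "fisher_exact_two_sided",
        float(odds),
        float(p),
        extra={"table": table,
               "freq_a": a_arg2 / a_total if a_total else np.nan,
               "freq_b": b_arg2 / b_total if b_total else np.nan},
    )
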