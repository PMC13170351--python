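"""Whole-pipeline validation studies with known ground truth.

Each function here re-runs a slice of the package against an independent
oracle — planted simulation truth, literal re-application of filter
criteria, exhaustive structure enumeration, or closed-form statistics —
and reports summary numbers.  They power both the validation test suite
and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import pileup as pe
from ._util import rng_for
from .annotate import can_pair, classify_window, fold_window
from .calling import StrandFilterParams, VariantCall, strand_conditional_filter
from .pileup import base_passes_quality
from .pipeline import discover_sites, run_simulation_study
from .simdata import (
    SimConfig,
    build_genome,
    mirror,
    simulate_dna_reads,
    simulate_rna_reads,
)
from .stats import arg2_codon_enrichment, bh_fdr, group_test

STUDY_RATES = (0.05, 0.1, 0.2, 0.4, 0.8)


def study_config(seed: int, **overrides) -> SimConfig:
    """The desk-scale study condition: 30 mixed-context sites at rates
    5-80%, 20 SNVs, strand-specific RNA at 100x with 0.2% error, matched
    60x DNA."""
    defaults = dict(
        seed=seed,
        n_features=15,
        n_edited_sites=30,
        editing_rates=STUDY_RATES,
        n_snvs=20,
        rna_depth=100.0,
        dna_depth=60.0,
        error_rate=0.002,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# 1. end-to-end recovery


def recovery_study(seeds=(1, 2, 3, 4, 5)) -> dict:
    """Recall over planted sites (rate >= 5%) and SNV leakage, per seed."""
    recalls, fps = [], []
    for seed in seeds:
        res = run_simulation_study(study_config(seed), annotate_result=False)
        recalls.append(res.recall)
        fps.append(res.snv_false_positives)
    return {
        "recall_per_seed": recalls,
        "recall_mean": float(np.mean(recalls)),
        "recall_min": float(np.min(recalls)),
        "snv_false_positives_total": int(np.sum(fps)),
        "n_seeds": len(list(seeds)),
    }


# ---------------------------------------------------------------------------
# 2. level accuracy


def level_accuracy(seed: int = 1, rna_depth: float = 200.0) -> dict:
    """Backfilled levels vs the realized edited-fragment fraction.

    The realized fraction (edited fragments / covering fragments, from
    read provenance) is what an exact measurement would report; the
    deviation of the backfilled level from it isolates measurement error
    (merging, quality filtering, orientation-consistent counting,
    sequencing errors) from binomial sampling noise.
    """
    cfg = study_config(seed, rna_depth=rna_depth, n_edited_sites=12, n_snvs=6)
    bundle, truth = build_genome(cfg)
    samples = {
        f"rep{r}": simulate_rna_reads(bundle, truth, cfg, f"rep{r}")
        for r in (1, 2, 3)
    }
    rna = {"c": {k: pe.reads_from_sample(s) for k, s in samples.items()}}
    dna = {"d": pe.reads_from_sample(simulate_dna_reads(bundle, truth, cfg, "d"))}
    disc = discover_sites(rna, dna, bundle)

    deltas = []
    site_by_pos = {s.genome_pos: s for s in truth.sites}
    for site in disc.sites:
        planted = site_by_pos.get(site.genome_pos - 1)
        if planted is None:
            continue
        for sid, sample in samples.items():
            level = site.levels.get(sid)
            if level is None:
                continue
            covering = carried = 0
            for prov in sample.provenance.values():
                gs, ge = prov.fragment
                if prov.feature_id == planted.feature_id and gs <= planted.genome_pos < ge:
                    covering += 1
                    carried += planted.genome_pos in prov.edited_positions
            if covering == 0:
                continue
            deltas.append(abs(level - 100.0 * carried / covering))
    deltas = np.asarray(deltas)
    return {
        "n_values": int(len(deltas)),
        "within_3pp_fraction": float(np.mean(deltas <= 3.0)),
        "max_abs_delta_pp": float(deltas.max()) if len(deltas) else float("nan"),
        "mean_abs_delta_pp": float(deltas.mean()) if len(deltas) else float("nan"),
    }


# ---------------------------------------------------------------------------
# 3. filter-cascade oracle


def literal_cascade(v: VariantCall, strand: str) -> bool:
    """The printed criteria, restated inequality by inequality."""
    if strand == "+":
        return (
            v.ref_base == "A" and v.alt_base == "G"
            and v.count_rev >= 3 and v.coverage_rev >= 10
            and v.frequency >= 1.0
            and v.unique_starts >= 3 and v.unique_ends >= 3
        )
    return (
        v.ref_base == "T" and v.alt_base == "C"
        and v.count_fwd >= 3 and v.coverage_fwd >= 10
        and v.frequency >= 1.0
        and v.unique_starts >= 3 and v.unique_ends >= 3
    )


def random_candidates(n: int, seed: int) -> list[tuple[VariantCall, str]]:
    rng = rng_for(seed, "bench-cascade")
    out = []
    for i in range(n):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        covf, covr = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        cf, cr = int(rng.integers(0, covf + 1)), int(rng.integers(0, covr + 1))
        total = covf + covr
        freq = 100.0 * (cf + cr) / total if total else 0.0
        v = VariantCall(
            i + 1, str(ref), str(alt), freq, cf, cr, covf, covr,
            int(rng.integers(0, 7)), int(rng.integers(0, 7)), "bench",
        )
        out.append((v, "+" if rng.random() < 0.5 else "-"))
    return out


def cascade_oracle(n: int = 1000, seed: int = 1) -> dict:
    cands = random_candidates(n, seed)
    accept = {v.genome_pos for v, s in cands if strand_conditional_filter(v, s)[0]}
    expect = {v.genome_pos for v, s in cands if literal_cascade(v, s)}
    return {
        "n_candidates": n,
        "set_equal": accept == expect,
        "n_accepted": len(accept),
        "n_disagreements": len(accept ^ expect),
    }


# ---------------------------------------------------------------------------
# 4. folding oracle


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    def rec(positions):
        if not positions:
            return 0
        i, rest = positions[0], positions[1:]
        best = rec(rest)
        for j in rest:
            if j - i > min_loop and can_pair(seq[i], seq[j]):
                inside = tuple(p for p in rest if p < j)
                inside = tuple(p for p in inside if p > i)
                outside = tuple(p for p in rest if p > j)
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(seq))))


def folding_oracle(n: int = 200, seed: int = 1, max_len: int = 12) -> dict:
    rng = rng_for(seed, "bench-fold")
    agree = 0
    for _ in range(n):
        ln = int(rng.integers(5, max_len + 1))
        seq = "".join(rng.choice(list("ACGU"), size=ln))
        if fold_window(seq).n_pairs == enumerate_max_pairs(seq):
            agree += 1
    arm = "AGGAG" + "CUACGCU" + "CUCCU"  # designed 5-bp stem / 7-nt loop
    state, stem_len = classify_window(arm, 7)
    return {
        "n_sequences": n,
        "n_agree": agree,
        "arm_fixture_state": state,
        "arm_fixture_stem_len": stem_len,
    }


# ---------------------------------------------------------------------------
# 5. statistics oracles


def _hypergeom_two_sided(a, b, c, d) -> float:
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = sps.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = sps.hypergeom.pmf(k, n, col1, row1)
        if pk <= obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def fisher_oracle(n_tables: int = 100, seed: int = 1) -> dict:
    rng = rng_for(seed, "bench-fisher")
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(1, 120, size=4))
        res = arg2_codon_enrichment(
            ["CGT" * a + "AAA" * b], ["CGT" * c + "AAA" * d]
        )
        worst = max(worst, abs(res.pvalue - _hypergeom_two_sided(a, b, c, d)))
    return {"n_tables": n_tables, "max_abs_error": worst}


def bh_oracle(n_vectors: int = 1000, seed: int = 1) -> dict:
    rng = rng_for(seed, "bench-bh")
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 50)))
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        stepup = p[order] * m / np.arange(1, m + 1)
        expect = np.minimum(np.minimum.accumulate(stepup[::-1])[::-1], 1.0)
        got = bh_fdr(p)[order]
        worst = max(worst, float(np.max(np.abs(got - expect))))
    return {"n_vectors": n_vectors, "max_abs_error": worst}


def t_test_type1(method: str, n_reps: int = 10_000, seed: int = 1,
                 alpha: float = 0.05) -> dict:
    """Monte-Carlo null rejection rate; Welch runs an unequal-variance null."""
    rng = rng_for(seed, "bench-t", method)
    n = 5
    sd_b = 3.0 if method == "welch_t" else 1.0
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(0.0, sd_b, n)
        res = group_test({"a": a, "b": b}, method=method)
        rejections += res.pvalue < alpha
    return {"n_reps": n_reps, "type1_rate": rejections / n_reps, "alpha": alpha}


# ---------------------------------------------------------------------------
# 6. strand symmetry


def strand_symmetry(seed: int = 1) -> dict:
    """Mirror the genome, rerun, and compare catalogs in transcript space."""
    cfg = study_config(seed, n_edited_sites=10, n_snvs=6, rna_depth=60.0,
                       error_rate=0.0)
    bundle, truth = build_genome(cfg)
    fwd = run_simulation_study(cfg, bundle_truth=(bundle, truth),
                               annotate_result=False)
    mb, mt = mirror(bundle, truth)
    rev = run_simulation_study(cfg, bundle_truth=(mb, mt), annotate_result=False)

    L = len(bundle.sequence)

    def catalog(res, mirrored):
        out = {}
        for s in res.discovery.sites:
            pos0 = s.genome_pos - 1
            strand = s.transcript_strand
            if mirrored:
                pos0 = L - 1 - pos0
                strand = "-" if strand == "+" else "+"
            levels = tuple(
                round(v, 6) if v is not None else None
                for _, v in sorted(s.levels.items())
            )
            out[(pos0, strand)] = levels
        return out

    c1, c2 = catalog(fwd, False), catalog(rev, True)
    inter = set(c1) & set(c2)
    union = set(c1) | set(c2)
    return {
        "n_sites_forward": len(c1),
        "n_sites_mirrored": len(c2),
        "identical_site_sets": set(c1) == set(c2),
        "identical_levels": all(c1[k] == c2[k] for k in inter),
        "jaccard": len(inter) / len(union) if union else 1.0,
    }


# ---------------------------------------------------------------------------
# 7. boundary behavior


def boundary_behavior() -> dict:
    """Every printed threshold passes at its value, fails one unit below."""
    checks = []

    def cand(**kw):
        base = dict(freq=1.0, cr=3, covr=10, us=3, ue=3)
        base.update(kw)
        return VariantCall(
            100, "A", "G", base["freq"], 0, base["cr"], 0, base["covr"],
            base["us"], base["ue"], "b",
        )

    sp = StrandFilterParams()
    checks.append(strand_conditional_filter(cand(), "+", sp)[0] is True)
    for below in (
        dict(freq=0.99), dict(cr=2), dict(covr=9), dict(us=2), dict(ue=2)
    ):
        checks.append(strand_conditional_filter(cand(**below), "+", sp)[0] is False)

    from .calling import CallParams, call_variants
    from .pileup import PileupColumn

    def column(ref_n, alt_n):
        col = PileupColumn(9, "A")
        col.counts["rev"]["A"] = ref_n
        col.counts["rev"]["G"] = alt_n
        col.start_sets["G"] = set(range(alt_n))
        col.end_sets["G"] = set(range(alt_n))
        return {9: col}

    cp = CallParams()
    checks.append(len(call_variants(column(2, 2), "b", cp)) == 1)  # coverage 4
    checks.append(len(call_variants(column(1, 2), "b", cp)) == 0)  # coverage 3
    checks.append(len(call_variants(column(98, 2), "b", cp)) == 1)  # count 2
    checks.append(len(call_variants(column(99, 1), "b", cp)) == 0)  # count 1

    q30 = [40] * 21
    q30[10] = 30
    checks.append(base_passes_quality(tuple(q30), 10) is True)  # central Q30
    q29 = list(q30)
    q29[10] = 29
    checks.append(base_passes_quality(tuple(q29), 10) is False)  # central Q29

    return {"n_checks": len(checks), "n_passed": int(sum(checks))}
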