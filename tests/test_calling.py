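"""Calling and the filter cascade against literal re-application oracles."""

import numpy as np
import pytest

from conftest import make_column
from editscan._util import rng_for
from editscan.calling import (
    CallParams,
    StrandFilterParams,
    VariantCall,
    backfill_levels,
    call_variants,
    editing_level,
    replicate_consensus,
    strand_conditional_filter,
    subtract_dna,
)
from editscan.simdata import Feature


def test_call_variants_threshold_boundaries():
    # coverage 3 with 2 alt: below minimum coverage
    pl = {9: make_column(9, "A", fwd={"A": 1}, rev={"G": 2})}
    assert call_variants(pl, "s") == []
    # coverage 1000 with a single alt read: below minimum count
    pl = {9: make_column(9, "A", rev={"A": 999, "G": 1})}
    assert call_variants(pl, "s") == []
    # exactly at all three floors: coverage 4, count 2, frequency 50%
    pl = {9: make_column(9, "A", rev={"A": 2, "G": 2})}
    calls = call_variants(pl, "s")
    assert len(calls) == 1 and calls[0].genome_pos == 10
    # positions above the coverage ceiling are ignored
    pl = {9: make_column(9, "A", rev={"A": 100_000, "G": 1000})}
    assert call_variants(pl, "s") == []


def test_call_variants_matches_inequality_oracle_on_random_columns():
    rng = rng_for(31, "callrand")
    params = CallParams()
    pileup = {}
    for pos in range(1000):
        ref = "ACGT"[int(rng.integers(4))]
        fwd = {b: int(rng.integers(0, 6)) for b in "ACGT"}
        rev = {b: int(rng.integers(0, 6)) for b in "ACGT"}
        pileup[pos] = make_column(pos, ref, fwd=fwd, rev=rev)
    calls = call_variants(pileup, "s", params)
    got = {(c.genome_pos, c.alt_base) for c in calls}
    expect = set()
    for pos, col in pileup.items():
        cov = sum(col.counts["fwd"].values()) + sum(col.counts["rev"].values())
        for alt in "ACGT":
            if alt == col.ref_base:
                continue
            n = col.counts["fwd"][alt] + col.counts["rev"][alt]
            if cov >= 4 and cov <= 100_000 and n >= 2 and 100.0 * n / cov >= 0.1:
                expect.add((pos + 1, alt))
    assert got == expect


def _candidate(
    ref="A", alt="G", freq=5.0, cf=0, cr=5, covf=0, covr=50, us=5, ue=5
):
    return VariantCall(100, ref, alt, freq, cf, cr, covf, covr, us, ue, "s")


def test_strand_filter_passes_exactly_at_printed_boundaries():
    v = _candidate(freq=1.0, cr=3, covr=10, us=3, ue=3)
    ok, rep = strand_conditional_filter(v, "+")
    assert ok and rep.first_failed is None
    for kwargs in (
        dict(cr=2), dict(covr=9), dict(freq=0.99), dict(us=2), dict(ue=2)
    ):
        base = dict(freq=1.0, cr=3, covr=10, us=3, ue=3)
        base.update(kwargs)
        ok, rep = strand_conditional_filter(_candidate(**base), "+")
        assert not ok and rep.first_failed is not None


def test_strand_filter_rejects_wrong_orientation():
    ok, rep = strand_conditional_filter(_candidate(ref="T", alt="C"), "+")
    assert not ok and rep.first_failed == "reference_is_A"
    ok, _ = strand_conditional_filter(
        _candidate(ref="T", alt="C", cf=5, covf=50, cr=0, covr=0), "-"
    )
    assert ok


def test_unknown_strand_routes_through_both_rules():
    ok, _ = strand_conditional_filter(
        _candidate(ref="T", alt="C", cf=5, covf=50, cr=0, covr=0), None
    )
    assert ok
    ok, _ = strand_conditional_filter(_candidate(ref="C", alt="T"), None)
    assert not ok


def _random_candidates(n, rng):
    out = []
    for i in range(n):
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        covf, covr = int(rng.integers(0, 30)), int(rng.integers(0, 30))
        cf = int(rng.integers(0, covf + 1))
        cr = int(rng.integers(0, covr + 1))
        total = covf + covr
        freq = 100.0 * (cf + cr) / total if total else 0.0
        out.append(
            VariantCall(
                i + 1, str(ref), str(alt), freq, cf, cr, covf, covr,
                int(rng.integers(0, 7)), int(rng.integers(0, 7)), "s",
            )
        )
    return out


def literal_cascade(v, strand, p=StrandFilterParams()):
    """Criterion-by-criterion restatement, independent of the implementation."""
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


def test_cascade_equals_literal_oracle_on_500_random_candidates():
    rng = rng_for(32, "cascade")
    cands = _random_candidates(500, rng)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in cands]
    got = {
        v.genome_pos
        for v, s in zip(cands, strands)
        if strand_conditional_filter(v, s)[0]
    }
    expect = {
        v.genome_pos for v, s in zip(cands, strands) if literal_cascade(v, s)
    }
    assert got == expect


def test_raising_frequency_threshold_never_adds_sites():
    rng = rng_for(33, "mono")
    cands = _random_candidates(300, rng)
    loose = StrandFilterParams(min_frequency_pct=1.0)
    tight = StrandFilterParams(min_frequency_pct=5.0)
    for strand in "+-":
        pass_loose = {
            v.genome_pos for v in cands
            if strand_conditional_filter(v, strand, loose)[0]
        }
        pass_tight = {
            v.genome_pos for v in cands
            if strand_conditional_filter(v, strand, tight)[0]
        }
        assert pass_tight <= pass_loose


def test_dna_subtraction_removes_shared_keys_only():
    rna = [_candidate(), _candidate()]
    rna[1].genome_pos = 200
    dna = [_candidate()]
    dna[0].frequency = 50.0
    kept, removed = subtract_dna(rna, dna)
    assert [c.genome_pos for c in kept] == [200]
    assert removed[0][0].genome_pos == 100 and removed[0][1].frequency == 50.0


def test_consensus_thresholds_and_row_sum_oracle():
    v = _candidate()
    reps = {
        "r1": [(v, "+")],
        "r2": [(v, "+")],
        "r3": [],
    }
    cons = replicate_consensus(reps)
    assert cons == [((100, "G", "+"), ["r1", "r2"])]
    reps["r3"] = [(v, "+")]
    cons = replicate_consensus(reps)
    assert cons[0][1] == ["r1", "r2", "r3"]
    assert replicate_consensus({"r1": [(v, "+")], "r2": []}) == []
    with pytest.raises(ValueError, match="min_shared=1"):
        replicate_consensus({"r1": [(v, "+")]})

    # random incidence matrices vs a row-sum >= 2 oracle
    rng = rng_for(34, "consensus")
    for _ in range(20):
        inc = rng.random((15, 3)) < 0.5
        reps = {
            f"r{j}": [
                (VariantCall(i + 1, "A", "G", 5.0, 0, 5, 0, 50, 5, 5, f"r{j}"), "+")
                for i in range(15)
                if inc[i, j]
            ]
            for j in range(3)
        }
        cons = {key[0] for key, _ in replicate_consensus(reps)}
        expect = {i + 1 for i in range(15) if inc[i].sum() >= 2}
        assert cons == expect


def test_editing_level_ratio_and_orientation():
    col = make_column(99, "A", rev={"A": 90, "G": 10}, fwd={"A": 7, "G": 100})
    level, ocov = editing_level(col, "+")
    assert level == pytest.approx(10.0) and ocov == 100
    col2 = make_column(99, "T", fwd={"T": 30, "C": 10})
    level, _ = editing_level(col2, "-")
    assert level == pytest.approx(25.0)
    assert editing_level(None, "+") == (None, 0)


def test_backfill_reports_levels_lowcov_flags_and_missing_data():
    feats = [Feature("g", 50, 200, "+")]
    consensus = [((100, "G", "+"), ["r1", "r2"])]
    pileups = {
        "r1": {99: make_column(99, "A", rev={"A": 90, "G": 10})},
        "r2": {99: make_column(99, "A", rev={"A": 8, "G": 1})},
        "r3": {},  # site absent from this sample's pileup
    }
    sites = backfill_levels(consensus, pileups, feats)
    assert len(sites) == 1
    s = sites[0]
    assert s.feature_id == "g" and s.transcript_strand == "+"
    assert s.levels["r1"] == pytest.approx(10.0)
    assert not s.low_coverage["r1"]
    assert s.levels["r2"] == pytest.approx(100.0 / 9.0)
    assert s.low_coverage["r2"]  # 9 orientation-consistent reads < 10
    assert s.levels["r3"] is None  # missing data, distinct from 0%


def test_backfill_zero_alt_reads_is_level_zero_not_missing():
    feats = [Feature("g", 50, 200, "+")]
    consensus = [((100, "G", "+"), ["r1"])]
    pileups = {"r1": {99: make_column(99, "A", rev={"A": 50})}}
    sites = backfill_levels(consensus, pileups, feats)
    assert sites[0].levels["r1"] == 0.0
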