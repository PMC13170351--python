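"""Context extraction, motif logic, logo arithmetic, and folding against
exhaustive structure enumeration."""

import itertools

import numpy as np
import pytest

from editscan._util import dna_to_rna, revcomp, rng_for
from editscan.annotate import (
    SiteContext,
    WindowUnavailableError,
    build_logo,
    can_pair,
    classify_edited_position,
    classify_site_structure,
    classify_window,
    extract_context,
    fold_window,
    fold_window_rnafold,
    is_uacg,
    site_windows,
)


# ---------------------------------------------------------------------------
# context


def test_plus_strand_context_reads_uacg():
    #            0123456789
    genome = "CCCCCTACGGCCCC" + "A" * 100
    # edited A at genome position 6 (TACG at 5..8)
    ctx = extract_context(genome, 6, "+", flank=3)
    assert ctx.context_seq == "CCUACGG"
    assert ctx.context_seq[ctx.offset_of_A] == "A"
    assert is_uacg(ctx)


def test_minus_strand_context_equals_plus_case():
    # genomic CGTA read on the reverse strand is UACG
    genome = "GGGCGTAGGG" + "A" * 100
    # reverse-strand transcript: edited A pairs with genomic T at position 5
    ctx = extract_context(genome, 5, "-", flank=2)
    assert ctx.context_seq[1:5][:3]  # sanity
    assert ctx.context_seq[ctx.offset_of_A] == "A"
    assert is_uacg(ctx)


def test_random_contexts_match_revcomp_slice_oracle():
    rng = rng_for(41, "ctx")
    genome = "".join(rng.choice(list("ACGT"), size=500))
    for _ in range(50):
        flank = int(rng.integers(2, 9))
        pos = int(rng.integers(flank, 500 - flank))
        for strand in "+-":
            window = genome[pos - flank : pos + flank + 1]
            expect = dna_to_rna(window if strand == "+" else revcomp(window))
            if expect[flank] != "A":
                continue
            ctx = extract_context(genome, pos, strand, flank)
            assert ctx.context_seq == expect


def test_context_refuses_to_pad_past_genome_end():
    genome = "A" * 100
    with pytest.raises(WindowUnavailableError, match="exceeds"):
        extract_context(genome, 2, "+", flank=5)
    with pytest.raises(WindowUnavailableError):
        extract_context(genome, 98, "+", flank=5)


def test_exactly_one_of_256_four_mers_is_uacg():
    hits = []
    for mer in itertools.product("ACGU", repeat=4):
        if mer[1] != "A":
            continue
        ctx = SiteContext(0, "+", "G" + "".join(mer) + "G", 2)
        if is_uacg(ctx):
            hits.append("".join(mer))
    assert hits == ["UACG"]


# ---------------------------------------------------------------------------
# logo


def test_identical_contexts_give_two_bits_everywhere():
    ctxs = [SiteContext(0, "+", "GUACGU", 2) for _ in range(5)]
    logo = build_logo(ctxs)
    assert np.allclose(logo.info_bits.values, 2.0)
    assert np.allclose(logo.freqs.sum(axis=1), 1.0)


def test_uniform_column_has_zero_information():
    seqs = ["AACGU", "CACGU", "GACGU", "UACGU"]
    ctxs = [SiteContext(0, "+", s, 1) for s in seqs]
    logo = build_logo(ctxs)
    assert logo.info_bits.iloc[0] == pytest.approx(0.0)
    assert logo.info_bits.iloc[2] == pytest.approx(2.0)


def test_logo_ic_matches_direct_entropy_and_stays_in_bounds():
    rng = rng_for(42, "logo")
    width, n = 7, 100
    seqs = []
    for _ in range(n):
        s = list("".join(rng.choice(list("ACGU"), size=width)))
        s[3] = "A"
        seqs.append("".join(s))
    ctxs = [SiteContext(0, "+", s, 3) for s in seqs]
    logo = build_logo(ctxs)
    for i in range(width):
        col = [s[i] for s in seqs]
        freqs = np.array([col.count(b) / n for b in "ACGU"])
        h = -sum(f * np.log2(f) for f in freqs if f > 0)
        assert logo.info_bits.iloc[i] == pytest.approx(2.0 - h)
    assert ((logo.info_bits >= 0) & (logo.info_bits <= 2)).all()


def test_mixing_uniform_noise_decreases_information():
    rng = rng_for(43, "logo2")
    motif = [SiteContext(0, "+", "GUACGUG", 2) for _ in range(60)]
    noise = []
    for _ in range(60):
        s = list("".join(rng.choice(list("ACGU"), size=7)))
        s[2] = "A"
        noise.append(SiteContext(0, "+", "".join(s), 2))
    prev = None
    for k in (0, 20, 40, 60):
        ic = build_logo(motif + noise[:k]).info_bits.sum()
        if prev is not None:
            assert ic <= prev + 1e-9
        prev = ic


# ---------------------------------------------------------------------------
# folding


def enumerate_max_pairs(seq, min_loop=3):
    """Exhaustive maximum over all valid non-crossing structures (<= ~12 nt)."""
    n = len(seq)

    def rec(positions):
        best = 0
        if not positions:
            return 0
        i = positions[0]
        rest = positions[1:]
        best = rec(rest)  # i unpaired
        for jdx, j in enumerate(rest):
            if j - i > min_loop and can_pair(seq[i], seq[j]):
                inside = tuple(p for p in rest if i < p < j)
                outside = tuple(p for p in rest if p > j)
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(n)))


def validate_structure(seq, db, min_loop=3):
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs.append((j, i))
    assert not stack
    for i, j in pairs:
        assert can_pair(seq[i], seq[j])
        assert j - i > min_loop
    return len(pairs)


def test_fold_trivial_cases():
    fr = fold_window("AAAAA")
    assert fr.dot_bracket == "....." and fr.n_pairs == 0
    fr = fold_window("GGGAAAACCC")
    assert fr.n_pairs == 3
    assert fr.dot_bracket == "(((....)))"
    assert fr.n_pairs == enumerate_max_pairs("GGGAAAACCC")


def test_invalid_alphabet_is_an_error():
    with pytest.raises(ValueError):
        fold_window("GGGTAAACCC")  # T is DNA


def test_nussinov_matches_exhaustive_enumeration():
    rng = rng_for(44, "fold")
    for _ in range(60):
        n = int(rng.integers(5, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        fr = fold_window(seq)
        assert validate_structure(seq, fr.dot_bracket) == fr.n_pairs
        assert fr.n_pairs == enumerate_max_pairs(seq)


def test_reverse_complement_window_pairs_equally_without_wobble():
    """WC pairing mirrors under reverse complement; GU wobble cannot
    (the complement of a GU pair is AC, which does not pair)."""
    rng = rng_for(45, "foldrc")
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGU"), size=17))
        rc = "".join(comp[b] for b in reversed(seq))
        a = fold_window(seq, allow_gu=False)
        b = fold_window(rc, allow_gu=False)
        assert a.n_pairs == b.n_pairs


def test_designed_anticodon_arm_classifies_as_loop():
    """A 5-bp-stem / 7-nt-loop arm mimic: the edited A (window index 7,
    the wobble-position equivalent) must sit unpaired in a hairpin loop."""
    arm = "AGGAG" + "CUACGCU" + "CUCCU"  # stem + loop(UACG inside) + revcomp stem
    fr = fold_window(arm)
    assert fr.n_pairs == enumerate_max_pairs(arm)
    state, stem_len = classify_window(arm, 7)
    assert state == "loop_of_hairpin" and stem_len == 5

    # a GC-richer stem still traps the A in a loop, with a shorter
    # max-pairing stem because loop C/G bases offer alternative pairs
    arm2 = "GGCAG" + "CUACGCC" + "CUGCC"
    state2, stem2 = classify_window(arm2, 7)
    assert state2 == "loop_of_hairpin" and stem2 >= 2


def test_poly_a_context_is_not_stem_loop():
    genome = "A" * 1000
    ss = classify_site_structure(genome, 500, "+")
    assert not ss.stem_loop
    assert ss.fold17.edited_A_state == "unpaired_external"


def test_paired_position_classifies_as_paired():
    db = "(((....)))"
    assert classify_edited_position(db, 0) == ("paired", 0)
    state, stem = classify_edited_position(db, 4)
    assert state == "loop_of_hairpin" and stem == 3


def test_site_windows_anchor_geometry():
    genome = "".join("ACGT"[(i // 1) % 4] for i in range(200))
    w17, w37 = site_windows(genome, 100, "+", anchor="arm")
    assert len(w17) == 17 and len(w37) == 37
    assert w17[7] == dna_to_rna(genome[100])
    assert w37[18] == dna_to_rna(genome[100])
    w17c, _ = site_windows(genome, 100, "+", anchor="center")
    assert w17c[8] == dna_to_rna(genome[100])
    # '-' strand: transcript window is the reverse complement
    w17m, _ = site_windows(genome, 100, "-", anchor="arm")
    assert w17m[7] == dna_to_rna(revcomp(genome[100]))


def test_window_unavailable_is_flagged_not_padded():
    ss = classify_site_structure("A" * 1000, 3, "+")
    assert ss.window_unavailable and ss.fold17 is None


def test_planted_hairpin_sites_recover_stem_loop(small_study):
    truth_hp = {
        s.genome_pos + 1
        for s in small_study.truth.sites
        if s.context_kind == "UACG_hairpin"
    }
    ann = small_study.annotated
    rows = ann[ann.genome_pos.isin(truth_hp)]
    assert len(rows) > 0
    assert rows.stem_loop.mean() >= 0.9


def test_rnafold_backend_produces_same_shape():
    fr = fold_window_rnafold("GGGGAAAACCCC")
    assert len(fr.dot_bracket) == 12
    assert fr.n_pairs >= 3
    state, stem = classify_edited_position(fr.dot_bracket, 6)
    assert state in ("loop_of_hairpin", "paired", "unpaired_external")
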