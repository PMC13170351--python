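"""Sequence context, UACG motif, sequence-logo model, and hairpin classification.

Editing sites are annotated on the transcript strand: the context window
around the edited adenosine, whether the site sits in the UACG motif
(edited A second), a position-frequency/information-content logo model
over a set of contexts, and a secondary-structure class from folding the
17-nt (anticodon-arm-length) and 37-nt windows around the site.

The default folding model is Nussinov-style maximum base pairing
(Watson-Crick plus GU wobble, minimum hairpin loop of 3) with a
deterministic traceback.  It is a structural, not thermodynamic, model:
the question it answers is whether the edited A lies in the loop of a
stem-loop, the anticodon-arm-like geometry, and for that a maximum-pairing
criterion suffices and stays testable by exhaustive enumeration.  An
external thermodynamic backend (RNAfold) can be plugged in and its
dot-bracket is consumed by the same classifier.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import dna_to_rna, revcomp

_CAN_PAIR = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}

_RNA_BASES = ("A", "C", "G", "U")


class WindowUnavailableError(ValueError):
    """The requested context window extends past the genome end."""


# ---------------------------------------------------------------------------
# sequence context


@dataclass(frozen=True)
class SiteContext:
    """Transcript-strand context around an edited A (RNA alphabet)."""

    genome_pos: int  # 0-based position of the edited A on the genome
    strand: str
    context_seq: str
    offset_of_A: int

    def __post_init__(self):
        if self.context_seq[self.offset_of_A] != "A":
            raise ValueError("context_seq must carry A at offset_of_A")


def extract_context(
    genome_seq: str, genome_pos: int, strand: str, flank: int
) -> SiteContext:
    """Symmetric transcript-strand context with the edited A at ``flank``.

    For '-' strand sites the window is the reverse complement of the
    genomic slice, so the returned string always reads 5'->3' along the
    transcript.  Refuses to pad: a window extending past either genome
    end raises :class:`WindowUnavailableError` with the offending bounds.
    """
    lo, hi = genome_pos - flank, genome_pos + flank + 1
    if lo < 0 or hi > len(genome_seq):
        raise WindowUnavailableError(
            f"window [{lo}, {hi}) exceeds genome [0, {len(genome_seq)})"
        )
    window = genome_seq[lo:hi]
    if strand == "-":
        window = revcomp(window)
    return SiteContext(genome_pos, strand, dna_to_rna(window), flank)


def is_uacg(ctx: SiteContext) -> bool:
    """True iff the transcript-strand 4-mer starting one base 5' of the A is UACG."""
    i = ctx.offset_of_A - 1
    if i < 0 or i + 4 > len(ctx.context_seq):
        raise ValueError("context needs >= 1 nt 5' and >= 2 nt 3' of the A")
    return ctx.context_seq[i : i + 4] == "UACG"


# ---------------------------------------------------------------------------
# sequence logo


@dataclass
class LogoModel:
    """Position frequency matrix and per-position information content (bits)."""

    freqs: pd.DataFrame  # index: window offset, columns: A C G U
    info_bits: pd.Series
    n_contexts: int


def build_logo(contexts: list[SiteContext]) -> LogoModel:
    """Column base frequencies and IC_i = 2 - H_i over aligned contexts.

    No small-sample correction is applied; with a handful of sites the
    raw IC is what the motif figures of this field display.
    """
    if not contexts:
        raise ValueError("need at least one context")
    width = len(contexts[0].context_seq)
    offset = contexts[0].offset_of_A
    if any(len(c.context_seq) != width or c.offset_of_A != offset for c in contexts):
        raise ValueError("all contexts must share window length and A offset")
    counts = np.zeros((width, 4))
    col = {b: j for j, b in enumerate(_RNA_BASES)}
    for c in contexts:
        for i, b in enumerate(c.context_seq):
            counts[i, col[b]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    idx = pd.Index(np.arange(width) - offset, name="offset")
    return LogoModel(
        freqs=pd.DataFrame(freqs, index=idx, columns=list(_RNA_BASES)),
        info_bits=pd.Series(ic, index=idx, name="bits"),
        n_contexts=len(contexts),
    )


# ---------------------------------------------------------------------------
# folding


@dataclass
class FoldResult:
    window_seq: str
    dot_bracket: str
    n_pairs: int
    edited_A_state: str | None  # loop_of_hairpin | paired | unpaired_external
    stem_len: int  # pairs closing the loop (0 unless loop_of_hairpin)


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    if not allow_gu and {a, b} == {"G", "U"}:
        return False
    return (a, b) in _CAN_PAIR


def fold_window(seq: str, min_loop: int = 3, allow_gu: bool = True) -> FoldResult:
    """Maximum base-pairing structure of an RNA window.

    Nussinov dynamic program over Watson-Crick + GU wobble pairs with a
    minimum hairpin loop of ``min_loop`` unpaired bases.  Traceback is
    deterministic: at each interval, position i is paired with the
    smallest qualifying j that achieves the optimum, else left unpaired.
    GU wobble can be disabled; note only Watson-Crick-only folding is
    symmetric under reverse complement (the complement of a GU pair is
    AC, which does not pair).
    """
    seq = seq.upper()
    if set(seq) - set(_RNA_BASES):
        raise ValueError(f"sequence must be RNA over ACGU, got {set(seq) - set(_RNA_BASES)}")
    n = len(seq)
    if n < 5:
        raise ValueError("window must be >= 5 nt")
    dp = np.zeros((n + 1, n + 1), dtype=int)  # dp[i][j]: max pairs in seq[i..j]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(seq[i], seq[k], allow_gu):
                    cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0)
                    if cand > best:
                        best = cand
            dp[i][j] = best

    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(seq[i], seq[k], allow_gu):
                cand = 1 + dp[i + 1][k - 1] + (dp[k + 1][j] if k < j else 0)
                if cand == dp[i][j] and cand > dp[i + 1][j]:
                    pairs[i], pairs[k] = k, i
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    db = "".join(
        "(" if i in pairs and pairs[i] > i else ")" if i in pairs else "."
        for i in range(n)
    )
    return FoldResult(seq, db, len(pairs) // 2, None, 0)


def fold_window_rnafold(seq: str) -> FoldResult:
    """Thermodynamic MFE backend via the RNAfold executable (optional)."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=seq + "\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout.splitlines()
    db = out[1].split()[0]
    n_pairs = db.count("(")
    return FoldResult(seq, db, n_pairs, None, 0)


def _pair_table(db: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pairs


def classify_edited_position(db: str, offset: int) -> tuple[str, int]:
    """State of one position in a dot-bracket structure.

    Returns ``(state, stem_len)`` where state is ``paired``,
    ``loop_of_hairpin`` (unpaired inside a hairpin loop — an enclosing
    pair with no other pairs between its ends), or ``unpaired_external``
    (any other unpaired context: exterior, bulge, multiloop).  For a
    hairpin loop, ``stem_len`` counts the contiguous stacked pairs
    closing the loop.
    """
    pairs = _pair_table(db)
    if offset in pairs:
        return "paired", 0
    # find the innermost enclosing pair
    best: tuple[int, int] | None = None
    for i, j in pairs.items():
        if i < j and i < offset < j:
            if best is None or i > best[0]:
                best = (i, j)
    if best is None:
        return "unpaired_external", 0
    i, j = best
    if any(k in pairs for k in range(i + 1, j)):
        return "unpaired_external", 0  # enclosing region holds other pairs
    stem = 1
    while i - stem >= 0 and j + stem < len(db) and pairs.get(i - stem) == j + stem:
        stem += 1
    return "loop_of_hairpin", stem


def classify_window(seq_rna: str, offset: int, min_loop: int = 3) -> tuple[str, int]:
    """Fold a window and classify the position at ``offset``."""
    fr = fold_window(seq_rna, min_loop=min_loop)
    return classify_edited_position(fr.dot_bracket, offset)


@dataclass
class SiteStructure:
    fold17: FoldResult | None
    fold37: FoldResult | None
    stem_loop: bool
    window_unavailable: bool = False


def site_windows(
    genome_seq: str, genome_pos: int, strand: str, anchor: str = "arm"
) -> tuple[str, str]:
    """The 17-nt and 37-nt transcript-strand windows around an edited A.

    With the default ``arm`` anchor the 17-nt window copies the geometry
    of the tRNA-Arg2 anticodon arm, where the wobble A34 has 7 nt on its
    5' side and 9 nt on its 3' side; ``center`` places the A at 8/8.  The
    37-nt window is centred (18/18) under either anchor.
    """
    if anchor == "arm":
        left17, right17 = 7, 9
    elif anchor == "center":
        left17, right17 = 8, 8
    else:
        raise ValueError("anchor must be 'arm' or 'center'")

    def cut(left, right):
        if strand == "+":
            lo, hi = genome_pos - left, genome_pos + right + 1
        else:
            lo, hi = genome_pos - right, genome_pos + left + 1
        if lo < 0 or hi > len(genome_seq):
            raise WindowUnavailableError(
                f"window [{lo}, {hi}) exceeds genome [0, {len(genome_seq)})"
            )
        w = genome_seq[lo:hi]
        return dna_to_rna(w if strand == "+" else revcomp(w))

    return cut(left17, right17), cut(18, 18)


def classify_site_structure(
    genome_seq: str,
    genome_pos: int,
    strand: str,
    anchor: str = "arm",
    min_stem: int = 2,
    backend=fold_window,
) -> SiteStructure:
    """Fold both windows and flag stem-loop geometry of the edited A.

    ``stem_loop`` is true iff, in the 17-nt window, the edited A is
    unpaired inside a hairpin loop closed by a stem of >= ``min_stem``
    pairs.  Sites whose windows run off the genome are reported as
    window-unavailable, never silently padded.
    """
    try:
        w17, w37 = site_windows(genome_seq, genome_pos, strand, anchor)
    except WindowUnavailableError:
        return SiteStructure(None, None, False, window_unavailable=True)
    off17 = 7 if anchor == "arm" else 8
    f17 = backend(w17)
    f37 = backend(w37)
    state, stem = classify_edited_position(f17.dot_bracket, off17)
    f17.edited_A_state, f17.stem_len = state, stem
    state37, stem37 = classify_edited_position(f37.dot_bracket, 18)
    f37.edited_A_state, f37.stem_len = state37, stem37
    return SiteStructure(
        f17, f37, f17.edited_A_state == "loop_of_hairpin" and stem >= min_stem
    )
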