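"""Quality trimming and overlap merging of paired reads.

Trimming follows the modified-Mott algorithm: each base's error
probability p_i = 10^(-Q_i/10) is compared against an error-probability
limit (default 0.01), and the read is cut at the 3' end so that the kept
prefix maximises the running sum of (limit - p_i).  Reads with more than
one ambiguous base after trimming, or shorter than the minimum length,
are discarded.

Merging reverse-complements R2 into R1 orientation and scans ungapped
overlap offsets, scoring matches +1 and mismatches -2; an overlap is
accepted when its score reaches the minimum (8) and neither read
overhangs the other on the wrong side (no unaligned end mismatches).
Disagreeing overlap bases resolve to the higher-quality base.  Because
R1 is antisense to the transcript in this library layout, merged reads
keep that antisense orientation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp


@dataclass
class ReadRecord:
    read_id: str
    bases: str
    quals: tuple[int, ...]
    mate: str = "R1"  # R1 | R2 | merged

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError("bases and quals must have equal length")
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError("Phred values must lie in [0, 60]")


@dataclass(frozen=True)
class MergeParams:
    mismatch_cost: int = 2
    min_score: int = 8
    gap_cost: int = 3
    max_unaligned_end_mismatches: int = 0
    match_score: int = 1


def mott_cut_point(quals, quality_limit: float) -> int:
    """3'-cut index k maximising sum(limit - p_i) over the kept prefix.

    Ties resolve to the longest prefix.  Returns 0 when every cut gives a
    non-positive sum (whole read below the limit).
    """
    p = 10.0 ** (-np.asarray(quals, dtype=float) / 10.0)
    gain = np.concatenate([[0.0], np.cumsum(quality_limit - p)])
    best = float(gain.max())
    if best <= 0:
        return 0
    return int(np.flatnonzero(gain == best)[-1])


def quality_trim(
    read: ReadRecord,
    quality_limit: float = 0.01,
    min_len: int = 50,
    max_len: int = 150,
    max_ambiguities: int = 1,
) -> tuple[ReadRecord | None, str]:
    """Trim a read from its 3' end; returns (trimmed_or_None, reason).

    Reads are removed when, after trimming, they carry more than
    ``max_ambiguities`` ambiguous bases or fall below ``min_len``; reads
    longer than ``max_len`` are cut back to it rather than discarded.
    """
    k = mott_cut_point(read.quals, quality_limit)
    k = min(k, max_len)
    bases, quals = read.bases[:k], read.quals[:k]
    if sum(1 for b in bases if b not in "ACGT") > max_ambiguities:
        return None, "too_many_ambiguities"
    if len(bases) < min_len:
        return None, "below_min_length"
    return ReadRecord(read.read_id, bases, quals, read.mate), "kept"


def _overlap_score(a: str, b: str, d: int, params: MergeParams) -> tuple[int, int]:
    """(score, overlap_len) for r2' placed at offset d relative to r1."""
    lo = max(0, d)
    hi = min(len(a), d + len(b))
    if hi <= lo:
        return -(10**9), 0
    matches = mismatches = 0
    for i in range(lo, hi):
        if a[i] == b[i - d]:
            matches += 1
        else:
            mismatches += 1
    return matches * params.match_score - mismatches * params.mismatch_cost, hi - lo


def merge_pair(
    r1: ReadRecord, r2: ReadRecord, params: MergeParams = MergeParams()
) -> ReadRecord | None:
    """Merge an overlapping pair into one read in R1 orientation.

    Scans every ungapped offset of reverse-complemented R2 against R1 and
    keeps the best-scoring one; requires score >= ``min_score`` and an
    "innie" geometry (R2' may not start before R1 nor end inside it),
    which is the zero-unaligned-end-mismatches contract.  Ties between
    offsets resolve to the largest overlap; base conflicts resolve to the
    higher quality, ties toward R1.  Returns None when no offset
    qualifies.
    """
    if not r1.bases or not r2.bases:
        raise ValueError("cannot merge empty reads")
    b2 = revcomp(r2.bases)
    q2 = r2.quals[::-1]
    n1, n2 = len(r1.bases), len(b2)

    best_d, best_score = None, None
    for d in range(0, n1):
        if d + n2 < n1:
            continue  # R2' ends inside R1: overhanging-end mismatch
        score, _ = _overlap_score(r1.bases, b2, d, params)
        if score >= params.min_score and (best_score is None or score > best_score):
            best_d, best_score = d, score
    if best_d is None:
        return None

    d = best_d
    merged_len = d + n2
    bases, quals = [], []
    for i in range(merged_len):
        from1 = i < n1
        from2 = i >= d
        if from1 and from2:
            bq1, bq2 = (r1.bases[i], r1.quals[i]), (b2[i - d], q2[i - d])
            if bq1[0] == bq2[0]:
                bases.append(bq1[0])
                quals.append(max(bq1[1], bq2[1]))
            elif bq2[1] > bq1[1]:
                bases.append(bq2[0])
                quals.append(bq2[1])
            else:
                bases.append(bq1[0])
                quals.append(bq1[1])
        elif from1:
            bases.append(r1.bases[i])
            quals.append(r1.quals[i])
        else:
            bases.append(b2[i - d])
            quals.append(q2[i - d])
    return ReadRecord(r1.read_id, "".join(bases), tuple(quals), "merged")
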