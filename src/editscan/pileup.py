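"""Per-position, per-orientation base tallies with the neighborhood quality filter.

Aligned reads are reduced to pileup columns carrying, for each genome
position: base counts split by read orientation (forward / reverse on
the genome), per-orientation coverages, and — per supported base — the
number of distinct alignment start and end coordinates among the reads
carrying that base.  Those read-geometry counts feed the unique
start/end-position criteria of the editing filter cascade.

Broken pairs and multimappers are excluded read-wise; individual bases
are excluded when they fail the base-quality neighborhood filter
(central quality and the mean quality of the surrounding +/-5 window
both at least 30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import BASES
from .simdata import GenomeBundle, MateAlignment


@dataclass
class AlignedRead:
    """A gapless alignment; ``bases`` are stored genome-forward.

    ``cigar`` supports match (M/=/X) and soft-clip (S) operations only;
    None means all-match.  Soft-clipped bases contribute nothing to the
    pileup.
    """

    read_id: str
    genome_pos: int  # 0-based leftmost aligned position
    bases: str
    quals: tuple[int, ...]
    is_reverse: bool
    mapq: int = 60
    is_broken_pair: bool = False
    is_multimapper: bool = False
    cigar: str | None = None

    def aligned_span(self) -> tuple[int, int]:
        _, _, ref_len = _parse_cigar(self.cigar, len(self.bases))
        return self.genome_pos, self.genome_pos + ref_len


def _parse_cigar(cigar: str | None, read_len: int):
    """Returns (clip_left, clip_right, ref_len); validates consumption."""
    if cigar is None:
        return 0, 0, read_len
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    consumed = sum(n for n, op in ops)
    if consumed != read_len:
        raise ValueError(f"cigar {cigar} consumes {consumed} != read length {read_len}")
    clip_left = ops[0][0] if ops and ops[0][1] == "S" else 0
    clip_right = ops[-1][0] if len(ops) > 1 and ops[-1][1] == "S" else 0
    for n, op in ops:
        if op not in "MS=X":
            raise ValueError(f"unsupported cigar op {op!r}")
    return clip_left, clip_right, read_len - clip_left - clip_right


@dataclass(frozen=True)
class QualityFilterParams:
    neighborhood_radius: int = 5
    min_central_quality: int = 30
    min_neighborhood_quality: int = 30
    aggregation: str = "mean"  # 'mean' (default) or 'min'

    def __post_init__(self):
        if self.neighborhood_radius < 0:
            raise ValueError("radius must be >= 0")
        if self.aggregation not in ("mean", "min"):
            raise ValueError("aggregation must be 'mean' or 'min'")


def base_passes_quality(
    quals, offset: int, params: QualityFilterParams = QualityFilterParams()
) -> bool:
    """Central-quality and neighborhood-quality test for one read base.

    The neighborhood is the window of radius 5 around the base, clipped
    at the read ends; its aggregate (window mean by default, strict
    minimum optionally) must reach the neighborhood threshold.
    """
    if offset < 0 or offset >= len(quals):
        raise IndexError("offset outside read")
    if quals[offset] < params.min_central_quality:
        return False
    lo = max(0, offset - params.neighborhood_radius)
    hi = min(len(quals), offset + params.neighborhood_radius + 1)
    window = np.asarray(quals[lo:hi], dtype=float)
    agg = window.mean() if params.aggregation == "mean" else window.min()
    return bool(agg >= params.min_neighborhood_quality)


@dataclass
class PileupColumn:
    genome_pos: int  # 0-based
    ref_base: str
    counts: dict = field(
        default_factory=lambda: {o: {b: 0 for b in BASES} for o in ("fwd", "rev")}
    )
    start_sets: dict = field(default_factory=lambda: {b: set() for b in BASES})
    end_sets: dict = field(default_factory=lambda: {b: set() for b in BASES})

    @property
    def coverage_fwd(self) -> int:
        return sum(self.counts["fwd"].values())

    @property
    def coverage_rev(self) -> int:
        return sum(self.counts["rev"].values())

    @property
    def coverage(self) -> int:
        return self.coverage_fwd + self.coverage_rev

    def unique_start_positions(self, base: str) -> int:
        return len(self.start_sets[base])

    def unique_end_positions(self, base: str) -> int:
        return len(self.end_sets[base])


def build_pileup(
    reads: list[AlignedRead],
    genome: GenomeBundle | str,
    params: QualityFilterParams = QualityFilterParams(),
    mapq_floor: int = 1,
) -> dict[int, PileupColumn]:
    """Tally surviving read bases into per-position columns.

    Excludes broken-pair reads, explicit multimappers, and reads with
    mapping quality below ``mapq_floor``; excludes individual bases
    failing :func:`base_passes_quality`; skips soft-clipped bases and
    Ns.  Positions with zero surviving coverage are omitted.  Output is
    independent of read input order.
    """
    seq = genome.sequence if isinstance(genome, GenomeBundle) else genome
    columns: dict[int, PileupColumn] = {}
    for read in reads:
        if read.is_broken_pair or read.is_multimapper or read.mapq < mapq_floor:
            continue
        clip_l, clip_r, ref_len = _parse_cigar(read.cigar, len(read.bases))
        start, end = read.genome_pos, read.genome_pos + ref_len
        if start < 0 or end > len(seq):
            raise ValueError(f"read {read.read_id} extends past the genome")
        orient = "rev" if read.is_reverse else "fwd"
        for k in range(ref_len):
            off = clip_l + k
            base = read.bases[off]
            if base not in "ACGT":
                continue
            if not base_passes_quality(read.quals, off, params):
                continue
            pos = start + k
            col = columns.get(pos)
            if col is None:
                col = columns[pos] = PileupColumn(pos, seq[pos])
            col.counts[orient][base] += 1
            col.start_sets[base].add(start)
            col.end_sets[base].add(end)
    return dict(sorted(columns.items()))


def merge_aligned_pair(m1: MateAlignment, m2: MateAlignment) -> AlignedRead:
    """Combine two gapless mates of one fragment into a single read.

    The merged read spans both mates; where they overlap, disagreeing
    bases resolve to the higher quality (ties toward R1).  Orientation is
    inherited from R1, mirroring the FASTQ-level merge that keeps reads
    antisense to the transcript.
    """
    if m1.mate != 1:
        m1, m2 = m2, m1
    lo = min(m1.pos, m2.pos)
    hi = max(m1.pos + len(m1.seq_fwd), m2.pos + len(m2.seq_fwd))
    bases = [""] * (hi - lo)
    quals = np.full(hi - lo, -1, dtype=int)
    for m in (m2, m1):  # R1 second: wins quality ties
        for i, b in enumerate(m.seq_fwd):
            j = m.pos - lo + i
            q = m.quals_fwd[i]
            if q > quals[j] or (q == quals[j] and m.mate == 1):
                bases[j], quals[j] = b, q
    return AlignedRead(
        m1.read_id,
        lo,
        "".join(bases),
        tuple(int(q) for q in quals),
        is_reverse=m1.is_reverse,
        mapq=min(m1.mapq, m2.mapq),
    )


def reads_from_sample(sample, merge_pairs: bool = True) -> list[AlignedRead]:
    """AlignedReads from an in-memory simulated sample (see reads_from_mates)."""
    return reads_from_mates(sample.alignments, merge_pairs)


def reads_from_mates(
    mates: list[MateAlignment], merge_pairs: bool = True
) -> list[AlignedRead]:
    """AlignedReads from mate records (simulated or loaded from SAM).

    With ``merge_pairs`` (the default, matching the analysis contract)
    each fragment becomes one merged read in R1 orientation; otherwise
    the two mates are kept separate.  Unpaired mates are flagged broken.
    """
    by_id: dict[str, list[MateAlignment]] = {}
    for m in mates:
        by_id.setdefault(m.read_id, []).append(m)
    out: list[AlignedRead] = []
    for rid, mates in by_id.items():
        if merge_pairs and len(mates) == 2:
            out.append(merge_aligned_pair(*mates))
        else:
            for m in mates:
                out.append(
                    AlignedRead(
                        rid,
                        m.pos,
                        m.seq_fwd,
                        m.quals_fwd,
                        is_reverse=m.is_reverse,
                        mapq=m.mapq,
                        is_broken_pair=merge_pairs and len(mates) != 2,
                    )
                )
    out.sort(key=lambda r: (r.genome_pos, r.read_id))
    return out
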