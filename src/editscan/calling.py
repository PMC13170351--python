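"""Editing-site discovery: initial variant calls, the strand-conditional
filter cascade, DNA subtraction, replicate consensus, and level backfill.

The procedure mirrors how bacterial A-to-I sites are pulled out of
strand-specific RNA-seq: inosine reads as G, so true editing appears as
A->G mismatches on '+'-strand transcripts and T->C on '-'-strand ones.
In a reverse-oriented library (merged reads antisense to the transcript)
the orientation-consistent evidence for a '+'-strand transcript comes
from reverse-mapping reads, and from forward-mapping reads for a
'-'-strand transcript — hence the mirrored per-strand criteria.

Candidates surviving the cascade are cleared against matched DNA-seq
(a variant also present in DNA is a genomic SNV, not editing), required
in at least two replicates of a condition, and finally backfilled: the
editing level of every consensus site is re-extracted from the raw
pileups of every sample, including samples where the per-sample filters
failed, so a missing value means missing data rather than a filter
artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pileup import PileupColumn
from .simdata import Feature

_EDIT_ALT = {"+": ("A", "G"), "-": ("T", "C")}


@dataclass(frozen=True)
class CallParams:
    """Initial variant-calling thresholds."""

    min_coverage: int = 4
    min_count: int = 2
    min_frequency_pct: float = 0.1
    max_coverage: int = 100_000


@dataclass(frozen=True)
class StrandFilterParams:
    """Strand-conditional cascade thresholds (shared by both strands)."""

    min_oriented_count: int = 3
    min_oriented_coverage: int = 10
    min_frequency_pct: float = 1.0
    min_unique_starts: int = 3
    min_unique_ends: int = 3


@dataclass
class VariantCall:
    genome_pos: int  # 1-based, variant-table convention
    ref_base: str
    alt_base: str
    frequency: float  # percent of covering bases carrying alt
    count_fwd: int
    count_rev: int
    coverage_fwd: int
    coverage_rev: int
    unique_starts: int
    unique_ends: int
    sample_id: str

    @property
    def key(self) -> tuple[int, str]:
        return (self.genome_pos, self.alt_base)


@dataclass
class FilterReport:
    """Per-candidate trace: every evaluated criterion with its measured value."""

    criteria: list[tuple[str, float, float, bool]] = field(default_factory=list)

    def check(self, name: str, measured, threshold, passed: bool) -> bool:
        self.criteria.append((name, measured, threshold, bool(passed)))
        return bool(passed)

    @property
    def passed(self) -> bool:
        return all(ok for _, _, _, ok in self.criteria)

    @property
    def first_failed(self) -> str | None:
        for name, _, _, ok in self.criteria:
            if not ok:
                return name
        return None


@dataclass
class EditingSite:
    genome_pos: int  # 1-based
    transcript_strand: str
    feature_id: str
    levels: dict[str, float | None] = field(default_factory=dict)  # None = missing
    low_coverage: dict[str, bool] = field(default_factory=dict)
    supporting_samples: list[str] = field(default_factory=list)


def call_variants(
    pileup: dict[int, PileupColumn],
    sample_id: str,
    params: CallParams = CallParams(),
) -> list[VariantCall]:
    """One call per (position, alt) meeting the coverage/count/frequency floor.

    SNVs only: single-base substitutions against the reference, computed
    from quality-surviving counts.  Positions above ``max_coverage`` are
    ignored wholesale.
    """
    calls: list[VariantCall] = []
    for pos, col in pileup.items():
        cov = col.coverage
        if cov < params.min_coverage or cov > params.max_coverage:
            continue
        for alt in "ACGT":
            if alt == col.ref_base:
                continue
            n_fwd = col.counts["fwd"][alt]
            n_rev = col.counts["rev"][alt]
            n = n_fwd + n_rev
            if n < params.min_count:
                continue
            freq = 100.0 * n / cov
            if freq < params.min_frequency_pct:
                continue
            calls.append(
                VariantCall(
                    genome_pos=pos + 1,
                    ref_base=col.ref_base,
                    alt_base=alt,
                    frequency=freq,
                    count_fwd=n_fwd,
                    count_rev=n_rev,
                    coverage_fwd=col.coverage_fwd,
                    coverage_rev=col.coverage_rev,
                    unique_starts=col.unique_start_positions(alt),
                    unique_ends=col.unique_end_positions(alt),
                    sample_id=sample_id,
                )
            )
    return calls


def strand_conditional_filter(
    v: VariantCall,
    feature_strand: str | None,
    params: StrandFilterParams = StrandFilterParams(),
) -> tuple[bool, FilterReport]:
    """Apply the per-strand editing criteria to one candidate.

    '+' strand transcripts: reference A, variant G, with the
    reverse-read count/coverage criteria (reads antisense to a '+'
    transcript map reverse).  '-' strand: reference T, variant C with the
    forward-read criteria.  An unknown strand routes the candidate
    through both rules and passes if either does.
    """
    if feature_strand is None:
        ok_p, rep_p = strand_conditional_filter(v, "+", params)
        if ok_p:
            return True, rep_p
        return strand_conditional_filter(v, "-", params)
    if feature_strand not in "+-":
        raise ValueError("feature_strand must be '+', '-', or None")

    ref_want, alt_want = _EDIT_ALT[feature_strand]
    if feature_strand == "+":
        ocount, ocov, tag = v.count_rev, v.coverage_rev, "reverse"
    else:
        ocount, ocov, tag = v.count_fwd, v.coverage_fwd, "forward"

    rep = FilterReport()
    ok = rep.check(f"reference_is_{ref_want}", v.ref_base, ref_want, v.ref_base == ref_want)
    ok &= rep.check(f"variant_is_{alt_want}", v.alt_base, alt_want, v.alt_base == alt_want)
    ok &= rep.check(f"{tag}_read_count", ocount, params.min_oriented_count,
                    ocount >= params.min_oriented_count)
    ok &= rep.check(f"{tag}_read_coverage", ocov, params.min_oriented_coverage,
                    ocov >= params.min_oriented_coverage)
    ok &= rep.check("frequency_pct", v.frequency, params.min_frequency_pct,
                    v.frequency >= params.min_frequency_pct)
    ok &= rep.check("unique_start_positions", v.unique_starts, params.min_unique_starts,
                    v.unique_starts >= params.min_unique_starts)
    ok &= rep.check("unique_end_positions", v.unique_ends, params.min_unique_ends,
                    v.unique_ends >= params.min_unique_ends)
    return ok, rep


def subtract_dna(
    rna_calls: list[VariantCall], dna_calls: list[VariantCall]
) -> tuple[list[VariantCall], list[tuple[VariantCall, VariantCall]]]:
    """Keep only RNA candidates absent from the DNA call set.

    Removal is keyed on (position, alt base); returns (kept, removed)
    where each removed entry pairs the RNA candidate with the matching
    DNA call.
    """
    dna_by_key = {c.key: c for c in dna_calls}
    kept, removed = [], []
    for c in rna_calls:
        if c.key in dna_by_key:
            removed.append((c, dna_by_key[c.key]))
        else:
            kept.append(c)
    return kept, removed


def replicate_consensus(
    calls_by_replicate: dict[str, list[tuple[VariantCall, str]]],
    min_shared: int = 2,
) -> list[tuple[tuple[int, str, str], list[str]]]:
    """Sites present in at least ``min_shared`` replicates.

    ``calls_by_replicate`` maps replicate id to (call, transcript_strand)
    pairs that passed the cascade.  Returns [(key, supporting replicate
    ids)] where key = (1-based position, alt base, strand), sorted by
    position.
    """
    if len(calls_by_replicate) < 2 and min_shared > 1:
        raise ValueError(
            "replicate consensus needs >= 2 replicates; pass min_shared=1 "
            "to accept single-replicate calls"
        )
    support: dict[tuple[int, str, str], list[str]] = {}
    for rep_id, calls in calls_by_replicate.items():
        seen = {(c.genome_pos, c.alt_base, strand) for c, strand in calls}
        for key in seen:
            support.setdefault(key, []).append(rep_id)
    out = [
        (key, sorted(reps))
        for key, reps in support.items()
        if len(reps) >= min_shared
    ]
    out.sort(key=lambda kv: kv[0])
    return out


def editing_level(col: PileupColumn | None, strand: str) -> tuple[float | None, int]:
    """(level %, orientation-consistent coverage) at one site in one sample.

    Level = 100 * G / (A + G) over orientation-consistent reads only
    (reverse for '+', forward for '-'; genomic T/C for '-').  None when
    the position has no surviving pileup column at all (missing data,
    distinct from an observed 0%).
    """
    if col is None:
        return None, 0
    orient = "rev" if strand == "+" else "fwd"
    ref, alt = _EDIT_ALT[strand]
    a = col.counts[orient][ref]
    g = col.counts[orient][alt]
    ocov = col.counts[orient]
    total = sum(ocov.values())
    level = 100.0 * g / (a + g) if (a + g) > 0 else 0.0
    return level, total


def backfill_levels(
    consensus: list[tuple[tuple[int, str, str], list[str]]],
    pileups_by_sample: dict[str, dict[int, PileupColumn]],
    features: list[Feature],
    low_coverage_below: int = 10,
) -> list[EditingSite]:
    """Re-extract editing levels for every consensus site in every sample.

    Sites are assigned to the feature(s) whose strand matches the
    consensus key; levels come straight from the raw pileups so samples
    whose per-sample filters failed still report a value.  Coverage below
    ``low_coverage_below`` orientation-consistent reads raises the
    low-coverage flag rather than suppressing the value.
    """
    sites: list[EditingSite] = []
    for (pos1, _alt, strand), supporters in consensus:
        pos0 = pos1 - 1
        feat_ids = [
            f.feature_id
            for f in features
            if f.start <= pos0 < f.end and f.strand == strand
        ] or ["unannotated"]
        for fid in feat_ids:
            site = EditingSite(pos1, strand, fid, supporting_samples=list(supporters))
            for sample_id, pileup in pileups_by_sample.items():
                level, ocov = editing_level(pileup.get(pos0), strand)
                site.levels[sample_id] = level
                site.low_coverage[sample_id] = ocov < low_coverage_below
            sites.append(site)
    return sites


def sites_to_frame(sites: list[EditingSite]) -> pd.DataFrame:
    """Editing sites as a tidy table: one row per (site, feature)."""
    rows = []
    for s in sites:
        row = {
            "genome_pos": s.genome_pos,
            "strand": s.transcript_strand,
            "feature_id": s.feature_id,
            "n_supporting": len(s.supporting_samples),
        }
        for sample_id, level in s.levels.items():
            row[f"level_{sample_id}"] = np.nan if level is None else level
            row[f"lowcov_{sample_id}"] = s.low_coverage[sample_id]
        rows.append(row)
    return pd.DataFrame(rows)
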