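"""Synthetic genome, stranded transcriptome, and read simulation with planted truth.

Everything downstream of read alignment is exercised against data built
here: a small linear chromosome carrying sense, antisense, and tRNA
features; A-to-I editing sites planted at known per-site rates in chosen
sequence contexts (UACG embedded in a hairpin, UACG in an arbitrary
context, or non-UACG); genomic SNVs planted at known allele fractions;
and strand-specific paired-end RNA-seq plus unstranded DNA-seq reads with
controlled per-base errors and quality strings.

The library layout emulated is the "reverse" (dUTP-style) protocol: R1 is
antisense to the transcript, R2 sense.  All per-fragment randomness is
drawn in transcript coordinates from a stream keyed by
``(seed, module, sample_id, feature_id)``, so reverse-complementing the
genome and flipping every feature strand reproduces the identical reads
in transcript space — the strand-flip symmetry the caller tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import BASES, revcomp, rng_for

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONTEXT_KINDS = ("UACG_hairpin", "UACG_linear", "nonUACG")


class SimSizingError(ValueError):
    """Requested planted elements exceed the available feature space."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Feature:
    """A stranded transcribed interval on the genome (0-based, half-open)."""

    feature_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "mRNA"  # mRNA | antisense | tRNA

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: end must exceed start")
        if self.end - self.start < 60:
            raise ValueError(f"{self.feature_id}: features must be >= 60 nt")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """Reference sequence plus stranded feature annotation."""

    genome_id: str
    sequence: str
    features: list[Feature]

    def __post_init__(self):
        if len(self.sequence) < 1000:
            raise ValueError("genome must be >= 1000 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("genome contains ambiguity codes")
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("feature identifiers must be unique")
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise ValueError(f"{f.feature_id} outside genome bounds")

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def transcript_seq(self, feat: Feature) -> str:
        """Transcript-strand (5'->3') sequence of a feature."""
        s = self.sequence[feat.start : feat.end]
        return s if feat.strand == "+" else revcomp(s)


@dataclass(frozen=True)
class PlantedSite:
    feature_id: str
    genome_pos: int  # 0-based coordinate of the edited adenosine
    transcript_strand: str
    editing_rate: float
    context_kind: str


@dataclass(frozen=True)
class PlantedSNV:
    genome_pos: int  # 0-based
    ref_base: str
    alt_base: str
    dna_allele_fraction: float

    def __post_init__(self):
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")


@dataclass(frozen=True)
class ReadProvenance:
    feature_id: str
    fragment: tuple[int, int]  # genome interval, 0-based half-open
    edited_positions: tuple[int, ...]  # genome coordinates carried as G
    truncated: bool = False


@dataclass
class SimTruth:
    sites: list[PlantedSite]
    snvs: list[PlantedSNV]
    per_read_provenance: dict[str, ReadProvenance] = field(default_factory=dict)


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a desk-scale version of the study design: a dozen
    transcribed features sequenced strand-specifically at ~50x with 0.2%
    per-base error, matched by ~60x unstranded DNA from the same
    (virtual) sample.
    """

    seed: int = 0
    n_features: int = 12
    feature_len: int = 300
    n_antisense: int = 1
    n_edited_sites: int = 10
    editing_rates: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8)
    context_kinds: tuple[str, ...] = CONTEXT_KINDS
    n_snvs: int = 6
    snv_allele_fractions: tuple[float, ...] = (1.0, 0.5)
    rna_depth: float = 50.0
    dna_depth: float = 60.0
    read_len: int = 100
    fragment_len_mean: float = 150.0
    fragment_len_sd: float = 15.0
    error_rate: float = 0.002
    qual_high: int = 40
    qual_low: int = 12

    def __post_init__(self):
        for name in ("n_features", "n_edited_sites", "n_snvs", "n_antisense"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.read_len >= self.fragment_len_mean:
            raise ValueError("read_len must be below fragment_len_mean")
        for k in self.context_kinds:
            if k not in CONTEXT_KINDS:
                raise ValueError(f"unknown context kind {k!r}")
        for r in self.editing_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("editing rates must lie in [0, 1]")


@dataclass(frozen=True)
class MateAlignment:
    """One aligned mate, stored in genome-forward orientation (all-match)."""

    read_id: str
    mate: int  # 1 or 2
    pos: int  # 0-based leftmost
    seq_fwd: str
    quals_fwd: tuple[int, ...]
    is_reverse: bool
    mapq: int = 60


@dataclass
class SimulatedSample:
    """In-memory read set for one sample: FASTQ-ready reads + alignments."""

    sample_id: str
    reads_r1: list[tuple[str, str, tuple[int, ...]]]  # (id, seq, quals) as sequenced
    reads_r2: list[tuple[str, str, tuple[int, ...]]]
    alignments: list[MateAlignment]
    provenance: dict[str, ReadProvenance]


# ---------------------------------------------------------------------------
# genome construction

_HAIRPIN_STEMS = ("GGCAG", "GCGTG", "GGTGC", "GCCAG", "GGCTG", "GCACG")
_LOOP_FILL = "AACC"  # candidate bases for unconstrained loop positions


def _design_hairpin_arm(rng: np.random.Generator) -> str:
    """A 17-nt anticodon-arm mimic: 5-bp stem, 7-nt loop, edited A at index 7.

    The loop carries UACG (DNA: TACG) at window indices 6..9 so the
    edited A sits one base 3' of the U, mirroring the wobble position of
    the tRNA-Arg2 arm.  Designs are verified by the package's own folding
    model before planting.
    """
    from .annotate import classify_window  # late import: avoids cycle at load

    for _ in range(64):
        stem = _HAIRPIN_STEMS[rng.integers(len(_HAIRPIN_STEMS))]
        free = [ _LOOP_FILL[rng.integers(len(_LOOP_FILL))] for _ in range(3) ]
        loop = free[0] + "TACG" + free[1] + free[2]
        arm = stem + loop + revcomp(stem)
        state, stem_len = classify_window(arm.replace("T", "U"), 7)
        if state == "loop_of_hairpin" and stem_len >= 2:
            return arm
    raise RuntimeError("could not design a verifiable hairpin arm")


def build_genome(cfg: SimConfig) -> tuple[GenomeBundle, SimTruth]:
    """Generate genome + features and plant editing sites and SNVs.

    Deterministic for a fixed ``cfg.seed``.  Raises
    :class:`SimSizingError` if the requested number of sites or SNVs does
    not fit in the available feature space at the enforced spacing.
    """
    rng = rng_for(cfg.seed, "genome")
    spacer = 80
    margin = 25  # keep planted contexts and windows inside their feature

    seq: list[str] = []
    features: list[Feature] = []

    def emit_random(n):
        seq.extend(rng.choice(list(BASES), size=n))

    emit_random(spacer)
    for i in range(cfg.n_features):
        start = len(seq)
        emit_random(cfg.feature_len)
        strand = "+" if rng.random() < 0.5 else "-"
        kind = "tRNA" if i == cfg.n_features - 1 and cfg.n_features > 2 else "mRNA"
        features.append(Feature(f"gene{i:03d}", start, len(seq), strand, kind))
        emit_random(spacer)
    # antisense features overlapping the first sense features (cf. ptwF-as)
    for j in range(min(cfg.n_antisense, len(features))):
        host = features[j]
        if len(host) - 20 < 60:
            continue
        features.append(
            Feature(
                f"{host.feature_id}-as",
                host.start + 10,
                host.end - 10,
                "-" if host.strand == "+" else "+",
                "antisense",
            )
        )
    if len(seq) < 1000:
        emit_random(1000 - len(seq))
    genome = np.array(seq, dtype="<U1")

    # --- choose site positions: round-robin over features, >=40 nt apart
    site_positions: list[tuple[Feature, int]] = []
    taken: list[int] = []
    if cfg.n_edited_sites:
        slots: list[tuple[Feature, int]] = []
        for f in features:
            usable = np.arange(f.start + margin, f.end - margin)
            slots.extend((f, int(p)) for p in usable)
        rr: dict[str, list[int]] = {}
        order = sorted({f.feature_id for f, _ in slots})
        per_feat = {
            fid: [p for f, p in slots if f.feature_id == fid] for fid in order
        }
        feat_cycle = 0
        attempts = 0
        while len(site_positions) < cfg.n_edited_sites:
            attempts += 1
            if attempts > 10000:
                raise SimSizingError(
                    f"could only place {len(site_positions)} of "
                    f"{cfg.n_edited_sites} requested editing sites; "
                    "enlarge n_features or feature_len"
                )
            fid = order[feat_cycle % len(order)]
            feat_cycle += 1
            pool = per_feat[fid]
            if not pool:
                continue
            p = int(pool[rng.integers(len(pool))])
            if all(abs(p - q) >= 40 for q in taken):
                feat = next(f for f in features if f.feature_id == fid)
                site_positions.append((feat, p))
                taken.append(p)

    # --- write contexts and record truth
    sites: list[PlantedSite] = []
    for idx, (feat, p) in enumerate(site_positions):
        rate = cfg.editing_rates[idx % len(cfg.editing_rates)]
        kind = cfg.context_kinds[idx % len(cfg.context_kinds)]
        if kind == "UACG_hairpin":
            arm = _design_hairpin_arm(rng)  # transcript strand, A at index 7
            _write_transcript(genome, feat, p, arm, 7)
        elif kind == "UACG_linear":
            _write_transcript(genome, feat, p, "TACG", 1)
        else:  # nonUACG: transcript A preceded by a non-U base
            lead = "GAC"[rng.integers(3)]
            _write_transcript(genome, feat, p, lead + "A", 1)
        sites.append(
            PlantedSite(feat.feature_id, p, feat.strand, float(rate), kind)
        )

    # --- plant SNVs inside features, away from sites
    snvs: list[PlantedSNV] = []
    snv_taken: list[int] = []
    genic = [f for f in features if f.kind != "antisense"] or features
    attempts = 0
    while len(snvs) < cfg.n_snvs:
        attempts += 1
        if attempts > 10000:
            raise SimSizingError(
                f"could only place {len(snvs)} of {cfg.n_snvs} requested "
                "SNVs; enlarge n_features or feature_len"
            )
        feat = genic[int(rng.integers(len(genic)))]
        p = int(rng.integers(feat.start + margin, feat.end - margin))
        if any(abs(p - q) < 25 for q in taken):
            continue
        if any(abs(p - q) < 10 for q in snv_taken):
            continue
        frac = cfg.snv_allele_fractions[len(snvs) % len(cfg.snv_allele_fractions)]
        ref = str(genome[p])
        if len(snvs) % 2 == 0:
            # make half the SNVs mimic editing (transcript-strand A->G)
            tref, talt = "A", "G"
            if feat.strand == "-":
                tref, talt = _COMPL[tref], _COMPL[talt]
            genome[p] = tref
            ref, alt = tref, talt
        else:
            alt = [b for b in BASES if b != ref][int(rng.integers(3))]
        snvs.append(PlantedSNV(p, ref, alt, float(frac)))
        snv_taken.append(p)

    bundle = GenomeBundle("simchr", "".join(genome), list(features))
    return bundle, SimTruth(sites=sites, snvs=snvs)


def _write_transcript(
    genome: np.ndarray, feat: Feature, site_gpos: int, block: str, a_index: int
):
    """Write ``block`` (transcript-strand DNA) into the genome so that
    block position ``a_index`` lands on genome coordinate ``site_gpos``.

    Along a '-' feature the transcript runs in decreasing genome
    coordinates, so block bases are laid right-to-left and complemented.
    """
    for i, b in enumerate(block):
        if feat.strand == "+":
            genome[site_gpos + (i - a_index)] = b
        else:
            genome[site_gpos - (i - a_index)] = _COMPL[b]


def mirror(bundle: GenomeBundle, truth: SimTruth) -> tuple[GenomeBundle, SimTruth]:
    """Reverse-complement the genome and flip every feature strand.

    Transcript-strand content is unchanged: each planted site keeps its
    context and editing rate, only genome coordinates and strands mirror.
    """
    L = len(bundle.sequence)
    feats = [
        Feature(
            f.feature_id,
            L - f.end,
            L - f.start,
            "-" if f.strand == "+" else "+",
            f.kind,
        )
        for f in bundle.features
    ]
    mbundle = GenomeBundle(bundle.genome_id + "_rc", revcomp(bundle.sequence), feats)
    msites = [
        replace(
            s,
            genome_pos=L - 1 - s.genome_pos,
            transcript_strand="-" if s.transcript_strand == "+" else "+",
        )
        for s in truth.sites
    ]
    msnvs = [
        PlantedSNV(
            L - 1 - v.genome_pos,
            _COMPL[v.ref_base],
            _COMPL[v.alt_base],
            v.dna_allele_fraction,
        )
        for v in truth.snvs
    ]
    return mbundle, SimTruth(sites=msites, snvs=msnvs)


# ---------------------------------------------------------------------------
# read simulation


def _site_tpos(site_gpos: int, feat: Feature) -> int:
    if feat.strand == "+":
        return site_gpos - feat.start
    return feat.end - 1 - site_gpos


def _apply_errors(frag: list[str], quals: np.ndarray, rng, error_rate, qual_low):
    if error_rate <= 0:
        return
    mask = rng.random(len(frag)) < error_rate
    for i in np.flatnonzero(mask):
        alts = [b for b in BASES if b != frag[i]]
        frag[i] = alts[int(rng.integers(3))]
        quals[i] = qual_low


def simulate_rna_reads(
    bundle: GenomeBundle, truth: SimTruth, cfg: SimConfig, sample_id: str
) -> SimulatedSample:
    """Strand-specific paired RNA reads for one sample.

    Fragments are drawn per feature at ~``rna_depth`` coverage; each
    fragment overlapping a planted site carries the edited base
    (transcript-strand G) with probability ``editing_rate``, independently
    per fragment; planted SNVs are carried at their DNA allele fraction;
    per-base errors are applied after editing.  R1 is the reverse
    complement of the fragment's transcript-strand 3' end (antisense
    library orientation), R2 the sense 5' end.
    """
    sites_by_feat: dict[str, list[PlantedSite]] = {}
    for s in truth.sites:
        sites_by_feat.setdefault(s.feature_id, []).append(s)
    snvs_sorted = sorted(truth.snvs, key=lambda v: v.genome_pos)

    sample = SimulatedSample(sample_id, [], [], [], {})
    max_frag = int(2 * cfg.read_len - 8)

    for feat in sorted(bundle.features, key=lambda f: f.feature_id):
        rng = rng_for(cfg.seed, "rna", sample_id, feat.feature_id)
        tseq = bundle.transcript_seq(feat)
        flen = len(feat)
        n_frags = max(1, int(np.ceil(cfg.rna_depth * flen / cfg.fragment_len_mean)))
        feat_sites = sorted(
            sites_by_feat.get(feat.feature_id, []),
            key=lambda s: _site_tpos(s.genome_pos, feat),
        )
        feat_snvs = sorted(
            (v for v in snvs_sorted if feat.start <= v.genome_pos < feat.end),
            key=lambda v: _site_tpos(v.genome_pos, feat),
        )
        for i in range(n_frags):
            li = int(np.rint(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd)))
            li = max(cfg.read_len, min(li, max_frag))
            truncated = li > flen
            li = min(li, flen)
            t0 = int(rng.integers(0, flen - li + 1))
            frag = list(tseq[t0 : t0 + li])
            quals = np.full(li, cfg.qual_high, dtype=int)

            for v in feat_snvs:
                tp = _site_tpos(v.genome_pos, feat)
                if t0 <= tp < t0 + li:
                    if rng.random() < v.dna_allele_fraction:
                        alt = v.alt_base if feat.strand == "+" else _COMPL[v.alt_base]
                        frag[tp - t0] = alt
            edited: list[int] = []
            for s in feat_sites:
                tp = _site_tpos(s.genome_pos, feat)
                if t0 <= tp < t0 + li:
                    if rng.random() < s.editing_rate:
                        frag[tp - t0] = "G"
                        edited.append(s.genome_pos)
            _apply_errors(frag, quals, rng, cfg.error_rate, cfg.qual_low)

            rid = f"{sample_id}:{feat.feature_id}:{i}"
            _emit_pair(sample, rid, feat, t0, frag, quals, cfg, edited, truncated)
    return sample


def _emit_pair(sample, rid, feat, t0, frag, quals, cfg, edited, truncated):
    li = len(frag)
    L = min(cfg.read_len, li)
    tfrag = "".join(frag)
    # as-sequenced reads (R1 antisense to transcript)
    r1_seq = revcomp(tfrag)[:L]
    r1_quals = tuple(int(q) for q in quals[::-1][:L])
    r2_seq = tfrag[:L]
    r2_quals = tuple(int(q) for q in quals[:L])
    sample.reads_r1.append((rid, r1_seq, r1_quals))
    sample.reads_r2.append((rid, r2_seq, r2_quals))

    if feat.strand == "+":
        gs = feat.start + t0
        ge = gs + li
        gfrag, gquals = tfrag, quals
        m1 = MateAlignment(rid, 1, ge - L, gfrag[li - L :], tuple(int(q) for q in gquals[li - L :]), True)
        m2 = MateAlignment(rid, 2, gs, gfrag[:L], tuple(int(q) for q in gquals[:L]), False)
    else:
        ge = feat.end - t0
        gs = ge - li
        gfrag = revcomp(tfrag)
        gquals = quals[::-1]
        m1 = MateAlignment(rid, 1, gs, gfrag[:L], tuple(int(q) for q in gquals[:L]), False)
        m2 = MateAlignment(rid, 2, ge - L, gfrag[li - L :], tuple(int(q) for q in gquals[li - L :]), True)
    sample.alignments.extend((m1, m2))
    sample.provenance[rid] = ReadProvenance(
        feat.feature_id, (gs, ge), tuple(edited), truncated
    )


def simulate_dna_reads(
    bundle: GenomeBundle, truth: SimTruth, cfg: SimConfig, sample_id: str = "dna"
) -> SimulatedSample:
    """Unstranded paired DNA reads: SNVs at their allele fraction, never editing."""
    rng = rng_for(cfg.seed, "dna", sample_id)
    L = len(bundle.sequence)
    n_frags = max(1, int(np.ceil(cfg.dna_depth * L / cfg.fragment_len_mean)))
    snvs = sorted(truth.snvs, key=lambda v: v.genome_pos)
    sample = SimulatedSample(sample_id, [], [], [], {})
    max_frag = int(2 * cfg.read_len - 8)

    for i in range(n_frags):
        li = int(np.rint(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd)))
        li = max(cfg.read_len, min(li, max_frag, L))
        gs = int(rng.integers(0, L - li + 1))
        frag = list(bundle.sequence[gs : gs + li])
        quals = np.full(li, cfg.qual_high, dtype=int)
        for v in snvs:
            if gs <= v.genome_pos < gs + li:
                if rng.random() < v.dna_allele_fraction:
                    frag[v.genome_pos - gs] = v.alt_base
        _apply_errors(frag, quals, rng, cfg.error_rate, cfg.qual_low)
        flip = rng.random() < 0.5  # unstranded: R1 on either strand
        rid = f"{sample_id}:frag:{i}"
        gfrag = "".join(frag)
        Lr = min(cfg.read_len, li)
        left = MateAlignment(rid, 1 if not flip else 2, gs, gfrag[:Lr], tuple(int(q) for q in quals[:Lr]), False)
        right = MateAlignment(rid, 2 if not flip else 1, gs + li - Lr, gfrag[li - Lr :], tuple(int(q) for q in quals[li - Lr :]), True)
        sample.alignments.extend((left, right))
        seq_fwd_l, seq_rev_r = gfrag[:Lr], revcomp(gfrag[li - Lr :])
        q_l = tuple(int(q) for q in quals[:Lr])
        q_r = tuple(int(q) for q in quals[::-1][:Lr])
        if not flip:
            sample.reads_r1.append((rid, seq_fwd_l, q_l))
            sample.reads_r2.append((rid, seq_rev_r, q_r))
        else:
            sample.reads_r1.append((rid, seq_rev_r, q_r))
            sample.reads_r2.append((rid, seq_fwd_l, q_l))
        sample.provenance[rid] = ReadProvenance("genomic", (gs, gs + li), ())
    return sample
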