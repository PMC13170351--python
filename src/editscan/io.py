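"""File-format boundaries: FASTA, BED6, FASTQ, SAM, and the truth/site tables.

All genomic coordinates are 0-based half-open in memory; emitted tables
use 1-based inclusive positions (stated in each table's header line) to
match variant-table convention.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import phred_to_qualstr
from .simdata import (
    Feature,
    GenomeBundle,
    MateAlignment,
    PlantedSNV,
    PlantedSite,
    SimTruth,
    SimulatedSample,
)


def write_fasta(bundle: GenomeBundle, path) -> None:
    rec = SeqRecord(Seq(bundle.sequence), id=bundle.genome_id, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_bed6(features: list[Feature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"simchr\t{f.start}\t{f.end}\t{f.feature_id}\t0\t{f.strand}\n")


def read_bed6(path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            _, start, end, name, _, strand = line.rstrip("\n").split("\t")[:6]
            feats.append(Feature(name, int(start), int(end), strand))
    return feats


def write_fastq(reads, path) -> None:
    """Write (read_id, seq, quals) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{phred_to_qualstr(quals)}\n")


def read_fastq(path):
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            (rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
        )
    return out


def write_sam(sample: SimulatedSample, bundle: GenomeBundle, path) -> None:
    """Emit the sample's alignments as a coordinate-sorted SAM with @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": bundle.genome_id, "LN": len(bundle.sequence)}],
    }
    mates: dict[str, list[MateAlignment]] = {}
    for m in sample.alignments:
        mates.setdefault(m.read_id, []).append(m)
    segs = []
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rid, ms in mates.items():
            ms = sorted(ms, key=lambda m: m.mate)
            for m in ms:
                other = ms[1] if m is ms[0] else ms[0]
                a = pysam.AlignedSegment(fh.header)
                a.query_name = rid
                a.query_sequence = m.seq_fwd
                a.query_qualities = pysam.qualitystring_to_array(
                    phred_to_qualstr(m.quals_fwd)
                )
                a.reference_id = 0
                a.reference_start = m.pos
                a.mapping_quality = m.mapq
                a.cigarstring = f"{len(m.seq_fwd)}M"
                flag = 0x1 | 0x2
                flag |= 0x40 if m.mate == 1 else 0x80
                if m.is_reverse:
                    flag |= 0x10
                if len(ms) == 2:
                    if other.is_reverse:
                        flag |= 0x20
                    a.next_reference_id = 0
                    a.next_reference_start = other.pos
                    left = min(m.pos, other.pos)
                    right = max(m.pos + len(m.seq_fwd), other.pos + len(other.seq_fwd))
                    a.template_length = (right - left) * (1 if m.pos <= other.pos else -1)
                a.flag = flag
                segs.append(a)
        for a in sorted(segs, key=lambda s: (s.reference_start, s.query_name)):
            fh.write(a)


def read_sam_mates(path) -> list[MateAlignment]:
    """Load gapless primary alignments as genome-forward mate records."""
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            out.append(
                MateAlignment(
                    read_id=a.query_name,
                    mate=2 if a.is_read2 else 1,
                    pos=a.reference_start,
                    seq_fwd=a.query_alignment_sequence,
                    quals_fwd=tuple(int(q) for q in a.query_alignment_qualities),
                    is_reverse=a.is_reverse,
                    mapq=a.mapping_quality,
                )
            )
    return out


_TRUTH_HEADER = "# coordinates are 0-based\n"


def write_truth(truth: SimTruth, outdir) -> None:
    outdir = Path(outdir)
    with open(outdir / "sites.tsv", "w") as fh:
        fh.write(_TRUTH_HEADER)
        fh.write("feature_id\tgenome_pos\ttranscript_strand\tediting_rate\tcontext_kind\n")
        for s in truth.sites:
            fh.write(
                f"{s.feature_id}\t{s.genome_pos}\t{s.transcript_strand}"
                f"\t{s.editing_rate}\t{s.context_kind}\n"
            )
    with open(outdir / "snvs.tsv", "w") as fh:
        fh.write(_TRUTH_HEADER)
        fh.write("genome_pos\tref_base\talt_base\tdna_allele_fraction\n")
        for v in truth.snvs:
            fh.write(
                f"{v.genome_pos}\t{v.ref_base}\t{v.alt_base}\t{v.dna_allele_fraction}\n"
            )


def read_truth(outdir) -> SimTruth:
    outdir = Path(outdir)
    sites_df = pd.read_csv(outdir / "sites.tsv", sep="\t", comment="#")
    snvs_df = pd.read_csv(outdir / "snvs.tsv", sep="\t", comment="#")
    sites = [
        PlantedSite(r.feature_id, int(r.genome_pos), r.transcript_strand,
                    float(r.editing_rate), r.context_kind)
        for r in sites_df.itertuples()
    ]
    snvs = [
        PlantedSNV(int(r.genome_pos), r.ref_base, r.alt_base,
                   float(r.dna_allele_fraction))
        for r in snvs_df.itertuples()
    ]
    return SimTruth(sites=sites, snvs=snvs)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, phase, replicate, nucleic_acid, sam_path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "phase", "replicate", "nucleic_acid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad = set(df["nucleic_acid"]) - {"RNA", "DNA"}
    if bad:
        raise ValueError(f"nucleic_acid must be RNA or DNA, got {sorted(bad)}")
    return df
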