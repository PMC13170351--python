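"""Shared low-level helpers: sequence manipulation and seeded RNG streams."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")

BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def rng_for(seed: int, *tags) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by (seed, *tags).

    Streams are derived from a :class:`numpy.random.SeedSequence` whose
    entropy is the master seed plus a CRC32 digest of each tag, so adding
    a new sample or feature never perturbs the reads generated for
    existing ones.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def phred_to_qualstr(quals) -> str:
    """Phred integer array -> FASTQ quality string (Phred+33)."""
    return "".join(chr(int(q) + 33) for q in quals)


def qualstr_to_phred(qs: str) -> np.ndarray:
    return np.frombuffer(qs.encode(), dtype=np.uint8).astype(int) - 33
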