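"""Quality-trim a read and merge an overlapping pair.

Trimming is the modified-Mott algorithm (error-probability limit 0.01,
cut from the 3' end); merging reverse-complements R2 into R1 orientation
and accepts the best ungapped overlap scoring >= 8 (match +1,
mismatch -2).  Merged reads stay antisense to the transcript, which is
what the strand-conditional editing filters rely on.
"""

from editscan._util import revcomp
from editscan.readprep import ReadRecord, merge_pair, quality_trim

# a read with a low-quality 3' tail: Q40 body, Q2 tail
body, tail = 60, 15
read = ReadRecord("r1", "ACGT" * 15 + "A" * tail, (40,) * body + (2,) * tail)
trimmed, reason = quality_trim(read)
print(f"trim: {len(read.bases)} nt -> {len(trimmed.bases)} nt ({reason})")

# a fragment sequenced from both ends with a 20-nt overlap
fragment = "ATGGCTAAGCGTGACCTGATCCGTACGGTTAAACCCGGGTT"
r1 = ReadRecord("pair", revcomp(fragment)[:30], (40,) * 30, "R1")
r2 = ReadRecord("pair", fragment[:30], (40,) * 30, "R2")
merged = merge_pair(r1, r2)
print(f"merged length: {len(merged.bases)} (fragment was {len(fragment)})")
print(f"merged == fragment in R1 orientation: {merged.bases == revcomp(fragment)}")
print(
    "\nThe merged read reproduces the full fragment in R1 (antisense) "
    "orientation,\nso one fragment contributes exactly one read with one "
    "orientation downstream."
)
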