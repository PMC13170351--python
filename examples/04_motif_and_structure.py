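"""Motif and secondary-structure annotation around editing sites.

Sites are annotated on the transcript strand: the UACG motif (edited A
second), a sequence-logo model (position frequencies + information
content in bits), and a fold of the 17-nt window — the length of the
tRNA-Arg2 anticodon arm, with the edited A at the wobble-equivalent
offset (7 nt 5', 9 nt 3').
"""

from editscan.annotate import (
    build_logo,
    classify_window,
    extract_context,
    fold_window,
    is_uacg,
)
from editscan.simdata import SimConfig, build_genome

cfg = SimConfig(seed=1, n_edited_sites=9, context_kinds=("UACG_hairpin",))
bundle, truth = build_genome(cfg)

contexts = [
    extract_context(bundle.sequence, s.genome_pos, s.transcript_strand, flank=5)
    for s in truth.sites
]
print("transcript-strand contexts (edited A in the middle):")
for c in contexts:
    print(f"  {c.context_seq}   UACG motif: {is_uacg(c)}")

logo = build_logo(contexts)
print("\nper-position information content (bits, offset 0 = edited A):")
print(logo.info_bits.round(2).to_string())

arm = "AGGAG" + "CUACGCU" + "CUCCU"  # 5-bp stem, loop with UACG, edited A at 7
fr = fold_window(arm)
state, stem = classify_window(arm, 7)
print(f"\nanticodon-arm mimic: {arm}")
print(f"max-pairing fold:    {fr.dot_bracket}  ({fr.n_pairs} pairs)")
print(f"edited A state: {state}, closing stem {stem} bp")
print(
    "\nHigh information content at offsets -1..+2 reflects the UACG "
    "motif; the\nedited A of the arm mimic sits unpaired in a hairpin "
    "loop, the geometry the\ndeaminase recognizes on its natural tRNA "
    "substrate."
)
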