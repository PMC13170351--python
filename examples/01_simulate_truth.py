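"""Build a synthetic genome with planted editing sites and SNVs.

The generator lays out a small linear chromosome of stranded features
(including an antisense transcript overlapping its host gene), plants
A-to-I editing sites at known per-site rates in chosen sequence contexts,
and plants genomic SNVs.  Everything downstream is scored against this
truth.
"""

from editscan.simdata import SimConfig, build_genome

cfg = SimConfig(seed=1, n_edited_sites=6, n_snvs=4)
bundle, truth = build_genome(cfg)

print(f"genome: {len(bundle.sequence)} nt, {len(bundle.features)} features")
print("\nplanted editing sites (0-based genome coordinates):")
for s in truth.sites:
    print(
        f"  {s.feature_id:12s} pos {s.genome_pos:5d} strand {s.transcript_strand}"
        f"  rate {s.editing_rate:4.0%}  context {s.context_kind}"
    )
print("\nplanted genomic SNVs:")
for v in truth.snvs:
    print(
        f"  pos {v.genome_pos:5d}  {v.ref_base}->{v.alt_base}"
        f"  allele fraction {v.dna_allele_fraction}"
    )
print(
    "\nEach site's rate is the per-fragment probability that an RNA read "
    "carries G\ninstead of A; SNVs appear in both DNA and RNA at their "
    "allele fraction and\nmust be removed by DNA subtraction, never "
    "reported as editing."
)
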