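"""Classify edited-C windows by their hairpin (stem-loop) context.

APOBEC3 enzymes prefer a C at the 3' end of a 3-4 nt loop closed by a
stem: >= 2 perfect Watson-Crick pairs, or >= 4 pair positions containing
exactly one mismatch or one single-nucleotide bulge.  The predicate
reports the qualifying geometry; the exhaustive enumerator lists all of
them.
"""

from apoedit import enumerate_structures, stemloop_predicate

examples = {
    # loop AAC closed by pairs C:G and G:C -> perfect 2-pair stem
    "perfect tri-loop": "T" * 11 + "GCAACGC" + "T" * 13,
    # loop TTAC; pairs C:G, T:C (mismatch), A:T, G:C -> 4-pair stem, 1 defect
    "tetra-loop + mismatch": "A" * 8 + "GATCTTACGCTC" + "A" * 11,
    "no structure": "A" * 15 + "C" + "A" * 15,
}

for name, window in examples.items():
    call = stemloop_predicate(window)
    print(f"{name:>22}: qualifies={call.qualifies} loop={call.loop_len} "
          f"stem={call.stem_len} defect={call.defect}")
    print(f"{'':>22}  {len(enumerate_structures(window))} qualifying "
          "geometries enumerated")
# A qualifying call means the edited C could sit in an APOBEC3-preferred
# hairpin; the site passes the structural filter only if it also lies in
# an exon or UTR.
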