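"""Simple indel coding and supermatrix concatenation.

Codes the internal gap runs of a toy alignment into binary characters
(1 = exact run, ? = subsumed by a longer gap, 0 = otherwise) and appends
them to the nucleotide matrix with recorded character-set boundaries.
"""

import phylotraits as pt
from phylotraits.indels import AlignmentPartition

aln = AlignmentPartition("locus1", {
    "s1": "AC--GTAC",
    "s2": "AC--GTAC",
    "s3": "ACTTGTAC",
    "s4": "A----TAC",
})
for t, s in aln.sequences.items():
    print(f"  {t}  {s}")

coded = pt.simple_indel_coding(aln)
print("\ncoded characters:")
for ch in coded.characters:
    print(f"  span {ch.start}-{ch.end}: "
          + "  ".join(f"{t}={c}" for t, c in ch.codes))

sm = pt.concatenate_partitions([aln], [coded])
print(f"\nsupermatrix: {len(sm.sequences)} taxa x {sm.length} characters")
print(f"charsets   : {sm.charsets}")
print("\ns4's 5-column gap subsumes the shared 2-column gap, so s4 is '?'")
print("for the shorter character: it cannot witness that indel either way.")
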