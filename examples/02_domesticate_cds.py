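"""Remove an internal BsaI site from a coding sequence.

A CDS that spells Gly-Leu as GGT CTC contains a BsaI recognition site
that would be cut during assembly; one synonymous codon change destroys
it without touching the protein.
"""

from ggclone import translate
from ggclone.domesticate import domesticate_cds

cds = "ATG" + "GGTCTC" + "GCTGAAGATCTGAAA" + "TAA"  # M G L A E D L K *
result = domesticate_cds(cds)

print("input: ", cds)
print("output:", result.sequence.bases)
for e in result.edits:
    print(f"edit: codon {e.codon_index} {e.old_codon} -> {e.new_codon} (removed {e.motif_removed})")
print("protein before:", translate(cds))
print("protein after: ", translate(result.sequence.bases))
print("The edit changes one base in the Leu codon; the translation is")
print("identical and the sequence is now safe to clone as a building block.")
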