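"""Excise the SwaI integration cassette and verify by in silico PCR.

After assembly the plasmid is linearized with blunt-cutting SwaI; the
fragment carrying the selection marker and the transcription units is
the integration cassette, while kanR and the origin stay on the vector
fragment.  Colony PCR with the fixed verification primers spans the
whole assembled region, so the amplicon length reports what the slots
contain.
"""

import ggclone as gg
from ggclone.fixtures import FixtureConfig, gen_demo_toolkit

registry = gen_demo_toolkit(FixtureConfig(seed=11))
design = gg.AssemblyDesign(
    "pGGYL3",
    ["HUH", "P_GPD", "tHMG1", "T_Mig1", "P_TEF", "ERG12", "T_Lip1", "P_EXP", "ERG19", "T_Lip2"],
)
product, _ = gg.simulate_assembly(design, registry)

cassette, vector = gg.extract_cassette(product.sequence)
counts = cassette.feature_counts()
print(f"cassette: {len(cassette.sequence.bases)} bp, features:",
      {k: counts[k] for k in ("marker", "promoter", "cds", "terminator")})
print(f"vector fragment: {len(vector.core.bases)} bp, retains kanR:",
      vector.core.has_feature("kanR"), "and ori:", vector.core.has_feature("ori"))

empty = gg.in_silico_pcr(registry.backbones["pGGYL3"].sequence)
filled = gg.in_silico_pcr(product.sequence)
print(f"verification amplicon: {empty.length} bp on the empty backbone,")
print(f"{filled.length} bp on the product ({filled.length - empty.length:+d} bp,")
print("exactly the net length of parts swapped in for the lacZ stuffer).")
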