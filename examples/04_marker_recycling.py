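"""Recycle selection markers after integration.

loxP-flanked markers are removed by Cre recombinase, leaving a single
34-nt loxP scar; the hisG-URA3-hisG marker collapses to one hisG copy
by homologous recombination under 5-fluoroorotic acid counter-selection.
"""

import ggclone as gg
from ggclone.fixtures import FixtureConfig, gen_demo_toolkit

registry = gen_demo_toolkit(FixtureConfig(seed=11))

# Cre/loxP: LEU2 marker
p1, _ = gg.simulate_assembly(
    gg.AssemblyDesign("pGGYL1", ["LEU2", "P_GPD", "MrBBS", "T_Mig1"]), registry
)
after_cre = gg.cre_excise(p1.sequence)
print(f"Cre/loxP: removed {len(p1.sequence.bases) - len(after_cre.bases)} bp;",
      f"LEU2 present: {after_cre.has_feature('LEU2')};",
      f"loxP scars left: {len(after_cre.features('loxP'))}")

# hisG pop-out: HUH marker
p2, _ = gg.simulate_assembly(
    gg.AssemblyDesign("pGGYL1", ["HUH", "P_GPD", "MrBBS", "T_Mig1"]), registry
)
after_pop = gg.hisG_popout(p2.sequence)
print(f"hisG pop-out: removed {len(p2.sequence.bases) - len(after_pop.bases)} bp;",
      f"URA3 present: {after_pop.has_feature('URA3')};",
      f"hisG copies left: {len(after_pop.features('hisG'))}")
print("Both operations are one-shot: applying them again raises")
print("'nothing to excise', so a recycled locus cannot be re-excised.")
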