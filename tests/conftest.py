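import pytest

import ggclone as gg
from ggclone.fixtures import FixtureConfig, gen_demo_toolkit


@pytest.fixture(scope="session")
def config():
    return FixtureConfig(seed=11)


@pytest.fixture(scope="session")
def registry(config):
    return gen_demo_toolkit(config)


@pytest.fixture(scope="session")
def four_fragment_product(registry):
    design = gg.AssemblyDesign("pGGYL1", ["LEU2", "P_GPD", "MrBBS", "T_Mig1"])
    product, side = gg.simulate_assembly(design, registry)
    return design, product, side


@pytest.fixture(scope="session")
def ten_fragment_product(registry):
    design = gg.AssemblyDesign(
        "pGGYL3",
        ["HUH", "P_GPD", "tHMG1", "T_Mig1", "P_TEF", "ERG12", "T_Lip1", "P_EXP", "ERG19", "T_Lip2"],
    )
    product, side = gg.simulate_assembly(design, registry)
    return design, product, side
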