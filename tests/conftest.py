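import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bacpan.simulate import SimConfig, emit_proteomes, simulate


@pytest.fixture(scope="session")
def toy_sim():
    """Small 10-genome simulation with accessory turnover and planted
    niche families; shared by profile/niche/distance tests."""
    cfg = SimConfig(
        n_genomes=10, core_size=40, gain_rate=60.0, loss_rate=1.0,
        n_marine=4, planted_per_niche=3, planted_presence_fraction=0.5,
        n_species=2, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_prot_sim():
    """5-genome simulation with emitted proteomes (short sequences keep
    the all-against-all alignment stage fast)."""
    cfg = SimConfig(
        n_genomes=5, core_size=8, gain_rate=12.0, loss_rate=1.0,
        n_marine=2, planted_per_niche=1, planted_presence_fraction=1.0,
        n_species=2, seed=7,
    )
    result = simulate(cfg, with_cog=False)
    proteomes = emit_proteomes(
        result.matrix, identity_within_family=0.9, seed=7, length_range=(60, 120)
    )
    return result, proteomes
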