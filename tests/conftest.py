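import numpy as np
import pytest

from npcgold import AnalysisConfig, CommonFrameParticle, ParticleSet, SimParams
from npcgold.simulate import simulate_gold_particles


def make_set(xz_pairs, label="nup", npc_ids=None):
    """Build a ParticleSet from (x, z) pairs in nm."""
    particles = [
        CommonFrameParticle(
            particle_id=f"p{i}",
            npc_id=npc_ids[i] if npc_ids else f"npc{i % 5}",
            x_nm=float(x),
            z_nm=float(z),
        )
        for i, (x, z) in enumerate(xz_pairs)
    ]
    return ParticleSet(nup_label=label, particles=particles)


@pytest.fixture
def fast_cfg():
    return AnalysisConfig(bootstrap_B=200, rng_seed=0)


@pytest.fixture(scope="session")
def basket_set():
    """Asymmetric nucleoplasmic protein: ring R0=40 at Z0=-40, Gaussian blur."""
    return simulate_gold_particles(
        SimParams(
            R0_nm=40.0, Z0_nm=-40.0, symmetric=False,
            displacement_model="isotropic-normal", displacement_sd_nm=7.0, seed=11,
        ),
        label="basket",
    )


@pytest.fixture(scope="session")
def channel_set():
    """Symmetric channel protein: ring R0=25 at Z0=+/-5."""
    return simulate_gold_particles(
        SimParams(
            R0_nm=25.0, Z0_nm=5.0, symmetric=True,
            displacement_model="isotropic-normal", displacement_sd_nm=7.0, seed=12,
        ),
        label="channel",
    )
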