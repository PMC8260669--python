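import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")

from paleoevo import simulate as sim  # noqa: E402


@pytest.fixture(scope="session")
def sim_cfg():
    return sim.SimConfig(seed=101)


@pytest.fixture(scope="session")
def planted_genome(sim_cfg):
    """A 0.5 Mb chromosome with 20 planted elements of mixed age."""
    rng = sim.stage_rng(sim_cfg.seed, "fixture-genome")
    genome = sim.random_genome({"chr1": 500_000}, sim_cfg.background_gc, rng)
    ages = [0.0, 0.5e6, 2e6, 5e6]
    elements = [
        sim.simulate_ltr_element(ages[i % 4], sim_cfg,
                                 superfamily="copia" if i % 2 else "gypsy",
                                 rng=rng, element_id=f"elem{i:03d}")
        for i in range(20)
    ]
    sim.place_elements(genome, elements, rng, min_spacing=4000)
    mutated, truth = sim.insert_elements(genome, elements, sim_cfg)
    return mutated, elements, truth


@pytest.fixture(scope="session")
def wgd_sim(sim_cfg):
    """60 genes duplicated once at Ks 0.3, no loss."""
    genes = sim.random_gene_set(60, rng=sim.stage_rng(sim_cfg.seed, "genes"))
    return genes, sim.simulate_wgd(genes, sim_cfg, ks_targets=[0.3],
                                   rng=sim.stage_rng(sim_cfg.seed, "wgd"))


def reciprocal_overlap(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))
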