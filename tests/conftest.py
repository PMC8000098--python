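"""Shared fixtures: a tiny founder pool and a tiny end-to-end replicate."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from cunigs.founder_genome import GenomeConfig, simulate_founders
from cunigs.orchestrator import ExperimentConfig, _prepare_replicate, validate_config

logging.getLogger("cunigs").setLevel(logging.WARNING)


TINY_GENOME = dict(
    n_chromosomes=3,
    n_founder_haplotypes=120,
    n_candidate_sites=800,
    burn_in_generations=40,
    effective_size_schedule=((0, 60), (30, 40)),
)

TINY_SCHEME = dict(
    base_does=20,
    base_sires=10,
    selected_does_per_gen=10,
    selected_sires_per_gen=5,
    cohort_females=20,
    cohort_males=20,
    blup_generations=3,
    random_mating_generations=2,
    final_females=100,
    final_males=100,
)


def tiny_config(**overrides) -> ExperimentConfig:
    base = dict(
        genome=dict(TINY_GENOME),
        scheme=dict(TINY_SCHEME),
        hd_per_chromosome=200,
        n_replicates=1,
        seed=7,
    )
    base.update(overrides)
    return validate_config(ExperimentConfig(**base))


@pytest.fixture(scope="session")
def tiny_pool():
    cfg = GenomeConfig(seed=11, **TINY_GENOME)
    return simulate_founders(cfg, min_segregating_per_chromosome=250)


@pytest.fixture(scope="session")
def tiny_world():
    """One tiny replicate's pedigree, gametes, panel, architecture and map."""
    cfg = tiny_config()
    ped, store, panel, arch, scheme, mask_seed, hd_cm = _prepare_replicate(cfg, "QTN_44", 0)
    return {
        "config": cfg,
        "pedigree": ped,
        "store": store,
        "panel": panel,
        "arch": arch,
        "scheme": scheme,
        "mask_seed": mask_seed,
        "hd_cm": hd_cm,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
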