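import numpy as np
import pytest
from hypothesis import settings

from genomepam import GenomeSequence, find_genomic_targets
from genomepam.simulate import SimConfig, run_simulation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_genome():
    return GenomeSequence({"chr1": "AATTGGCCAC", "chr2": "ACGTACGT"})


@pytest.fixture(scope="session")
def ngg_run():
    """One seeded NGG-model simulation shared across tests.

    Returns (config, genome, truth, captured sites, background templates).
    """
    cfg = SimConfig(seed=11, n_perfect_targets=900, n_mismatch_targets=180,
                    pam_model={"NGG": 1.0})
    genome, truth, sites = run_simulation(cfg)
    templates = find_genomic_targets(genome, cfg.spacer, max_mm=6)
    return cfg, genome, truth, sites, templates


def random_genome(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> GenomeSequence:
    alphabet = "ACGTN" if n_prob else "ACGT"
    p = [(1 - n_prob) / 4] * 4 + ([n_prob] if n_prob else [])
    seq = "".join(rng.choice(list(alphabet), size=length, p=p))
    return GenomeSequence({"chrR": seq})
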