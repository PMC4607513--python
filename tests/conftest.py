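import numpy as np
import pytest

from snpcontext import SimConfig, ancestral_records, plant_mutations, simulate_genome
from snpcontext.seqio import Genome


@pytest.fixture
def toy_genome():
    """60-bp two-compartment genome with a fully known sequence."""
    seq = "ACGTACGTACGTACGTACGTAACCGGTTACGTACGTACGTACGTACGTACGTACGTACGT"
    return Genome(
        contigs={"c1": seq},
        compartments=[("c1", 0, 30, "exonic"), ("c1", 30, 60, "intronic")],
    )


def null_simulation(seed: int, n_events: int = 2600, length: int = 300_000,
                    multipliers: dict | None = None) -> tuple:
    """One intergenic contig with planted ancestral SNPs; returns
    (genome, truth, A<->G records)."""
    cfg = SimConfig(
        seed=seed,
        contigs={"c1": [("intergenic", length)]},
        ancestral_count=n_events,
        quartet_multipliers=multipliers or {},
    )
    genome = simulate_genome(cfg)
    truth = plant_mutations(genome, cfg)
    return genome, truth, ancestral_records(genome, truth, canonical_class="AG")


@pytest.fixture(scope="session")
def null_ag_panel():
    """Session-wide null (multiplier-free) simulation with ~2,000 A<->G records."""
    return null_simulation(seed=11)
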