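import numpy as np
import pytest

from plastidkit.synthetic_data import (
    GenomeSpec,
    OperonSpec,
    ReadSimConfig,
    simulate_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_genome():
    """4.2-kb quadripartite genome with a few planted features."""
    spec = GenomeSpec(
        lsc_len=2000,
        ssc_len=600,
        ir_len=800,
        n_genes=2,
        seed=11,
        homopolymer_plants=[("A", 8), ("T", 7)],
        si_plants=[(13, 37)],
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def operon_genome():
    """Genome with four operons and four singleton genes."""
    ops = [
        OperonSpec(genes=[f"op{i}g{j}" for j in range(3)],
                   strand="+" if i % 2 == 0 else "-")
        for i in range(4)
    ]
    spec = GenomeSpec(
        lsc_len=16000, ssc_len=2500, ir_len=1500,
        n_genes=4, seed=21, operon_specs=ops,
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def midsize_genome_reads():
    """20.1-kb quadripartite genome with error-free 50x reads."""
    spec = GenomeSpec(lsc_len=14000, ssc_len=2500, ir_len=1800, n_genes=3, seed=7)
    genome = simulate_genome(spec)
    cfg = ReadSimConfig(
        depth=50, mean_len=380, hp_error_rate=0.0, sub_error_rate=0.0, seed=11
    )
    reads, truth = simulate_reads(genome, cfg)
    return genome, reads, truth


def tiling_fragments(seq: str, n_frags: int = 10, overlap: int = 500) -> list[str]:
    """Fragments tiling a circular sequence with the given end overlaps."""
    n = len(seq)
    doubled = seq + seq
    starts = np.linspace(0, n, n_frags + 1).astype(int)[:n_frags]
    frag_len = (n // n_frags) + overlap
    return [doubled[s : s + frag_len] for s in starts]
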