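import numpy as np
import pytest

from g4scape.simulate import SimConfig


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    """Random nucleotide string; ``p`` orders (A, C, G, T)."""
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), size=length, p=p))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale study configuration used by the closed-loop tests."""
    return SimConfig(
        seed=1,
        chrom_lengths=(("chr1", 30_000),),
        n_genes=8,
        n_ests=500,
        est_pg4_overlap_fraction=0.2,
        n_genes_per_expr_set=50,
        n_patients=20,
        n_mutations=500,
    )
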