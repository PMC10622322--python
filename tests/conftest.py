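import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from haplopept import synthetic_data as sd


@pytest.fixture(scope="session")
def small_proteome():
    """A small deterministic proteome with planted multivariant windows."""
    config = sd.SyntheticConfig(n_proteins=10, planted_pairs=4, seed=11)
    references, haplotypes, manifest = sd.generate_proteome(config)
    return config, references, haplotypes, manifest


@pytest.fixture(scope="session")
def micro_proteome():
    """Micro-scale proteome (5 genes) for exhaustive brute-force checks."""
    config = sd.SyntheticConfig(
        n_proteins=5,
        haplotypes_per_protein=4,
        planted_pairs=2,
        substitution_density=2.0,
        seed=23,
    )
    references, haplotypes, manifest = sd.generate_proteome(config)
    contaminants = sd.generate_contaminants(2, seed=23)
    return references, haplotypes, contaminants, manifest
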