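import numpy as np
import pytest

from utrscout import (
    SyntheticTruth,
    generate_coverage,
    generate_genome,
    plant_utrs,
)


@pytest.fixture(scope="session")
def small_study():
    """10-gene / 50 kb genome with one planted 50-nt, full-expression UTR
    per gene, plus exact (noise-free) coverage plateaus."""
    seed = 1
    sequence, genes = generate_genome(10, 50_000, seed=seed)
    utrs = plant_utrs(genes, 50_000, lengths=50, ratios=1.0, seed=seed)
    truth = SyntheticTruth(genes=genes, utrs=utrs, seed=seed)
    coverage = generate_coverage(truth, 50_000, mean_depth=100, noise_model="none")
    return sequence, truth, coverage


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
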