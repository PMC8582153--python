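import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tfdirect.simulate import SimConfig, simulate_dataset

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default synthetic bundle (seed 7), shared across the session."""
    cfg = SimConfig(seed=7)
    outdir = tmp_path_factory.mktemp("bundle")
    truth = simulate_dataset(cfg, outdir)
    return cfg, outdir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_annotation(rng, n_genes=50, n_chroms=3, span=500_000):
    """Random gene models (possibly overlapping) for property tests."""
    from tfdirect.genome import GeneModel, GenomeAnnotation

    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        length = int(rng.integers(500, 20_000))
        genes.append(
            GeneModel(
                gene_id=f"R{i:04d}",
                symbol=f"R{i:04d}",
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=start + length,
            )
        )
    return GenomeAnnotation(genes)
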