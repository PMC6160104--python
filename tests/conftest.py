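import numpy as np
import pytest

from cnvpop.io import CnvCall, SnpProbe
from cnvpop.cnvr import CnvRegion
from cnvpop.simulate import CnvTemplate, SimulationConfig, generate_cohort


def make_region(chrom="1", start=100, end=200, state="loss", carriers=("S1",)):
    return CnvRegion(
        chrom=chrom, start=start, end=end, state=state, carriers=frozenset(carriers)
    )


def random_calls(rng, n, chroms=("1", "2", "3"), max_pos=100_000, max_len=5_000, n_samples=20):
    calls = []
    for i in range(n):
        start = int(rng.integers(1, max_pos))
        length = int(rng.integers(1, max_len))
        calls.append(
            CnvCall(
                sample_id=f"S{rng.integers(n_samples)}",
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=start + length,
                tcn=int(rng.choice([0, 1, 3, 4])),
                n_snps=int(rng.integers(3, 50)),
            )
        )
    return calls


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Small two-population cohort with one strongly differentiated locus."""
    config = SimulationConfig(
        populations={"A": 30, "B": 30},
        n_chrom=2,
        chrom_length_bp=5_000_000,
        n_probes_per_chrom=200,
        lrr_sd=0.2,
        seed=11,
        templates=[
            CnvTemplate("1", 1_000_000, 1_500_000, 1, {"A": 0.9, "B": 0.1}),
            CnvTemplate("2", 2_000_000, 2_400_000, 3, {"A": 0.5, "B": 0.5}),
        ],
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
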