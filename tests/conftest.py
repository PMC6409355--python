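import numpy as np
import pytest

from oct4expr.genomic_io import TimeCourseRecord
from oct4expr.synthetic_data import GenerativeConfig, generate_timecourse

DAYS = (0, 1, 3, 5, 7, 11, 15, 18)


def random_records(rng: np.random.Generator, n_genes: int = 1,
                   days=DAYS) -> list[TimeCourseRecord]:
    """Records with random features and standard-normal expression."""
    out = []
    for g in range(n_genes):
        for d in days:
            out.append(TimeCourseRecord(
                gene_id=f"g{g}", day=d,
                height=float(rng.uniform(1, 10)),
                distance=float(rng.uniform(0, 1500)),
                width=float(rng.uniform(50, 500)),
                expression=float(rng.normal()),
            ))
    return out


@pytest.fixture
def noiseless_dataset():
    """Deterministic model data: expression exactly follows the model."""
    return generate_timecourse(GenerativeConfig(n_genes=10, noise_sd=0.0, seed=42))


@pytest.fixture
def noisy_dataset():
    return generate_timecourse(GenerativeConfig(n_genes=10, noise_sd=0.05, seed=42))
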