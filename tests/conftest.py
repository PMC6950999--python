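import numpy as np
import pandas as pd
import pytest

from dmppipe import (
    ChromSpec,
    PlantingSpec,
    default_sample_sheet,
    generate_dataset,
    generate_manifest,
)

TWO_CHROMS = [ChromSpec("chr1", 12_000_000), ChromSpec("chr2", 8_000_000)]


@pytest.fixture(scope="session")
def small_manifest():
    """2000 probes on two small chromosomes, with islands and genes."""
    return generate_manifest(2000, TWO_CHROMS, seed=7)


@pytest.fixture(scope="session")
def sheet():
    return default_sample_sheet()


@pytest.fixture(scope="session")
def planted_dataset(small_manifest, sheet):
    """Beta matrix with 120 planted DMPs at |delta beta| ~ 0.3 plus truth."""
    manifest, _, _ = small_manifest
    planting = PlantingSpec(n_planted=120, delta_mean=0.3, direction_mix=0.5)
    beta, truth = generate_dataset(manifest, sheet, planting, seed=11)
    return beta, truth


def make_random_cgis(rng: np.random.Generator, chrom: str, n: int, chrom_len: int) -> pd.DataFrame:
    """Non-overlapping random islands for classifier oracle tests."""
    lengths = rng.integers(200, 1200, size=n)
    gap = rng.integers(500, 20_000, size=n)
    starts = np.cumsum(gap + np.concatenate(([0], lengths[:-1])))
    starts = starts[starts + lengths < chrom_len]
    lengths = lengths[: len(starts)]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts.astype(int),
            "end": (starts + lengths - 1).astype(int),
            "cgi_id": [f"CGI_{chrom}_{i}" for i in range(len(starts))],
        }
    )
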