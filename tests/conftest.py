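import numpy as np
import pandas as pd
import pytest

from chemotrace.spectra_io import SpectraSet
from chemotrace.synthetic_data import (
    SyntheticDesign,
    class_mean_table,
    generate_dataset,
)


def make_spectra_set(
    n: int = 6,
    p: int = 12,
    k: int = 2,
    seed: int = 0,
    processed: bool = False,
    species: str = "sp",
) -> SpectraSet:
    """Random valid SpectraSet with roughly balanced origin classes."""
    rng = np.random.default_rng(seed)
    ids = [f"{species}_{i:03d}" for i in range(n)]
    energies = np.cumsum(rng.uniform(0.001, 0.01, p))
    values = rng.normal(0.0, 1.0, (n, p)) if processed else rng.uniform(0.0, 100.0, (n, p))
    origins = [f"class_{i % k + 1}" for i in range(n)]
    meta = pd.DataFrame(
        {"sample_id": ids, "species": species, "origin": origins}
    ).set_index("sample_id")
    return SpectraSet(
        sample_ids=ids,
        channel_energies=energies,
        intensities=values,
        meta=meta,
        processed=processed,
    )


def small_signal_design(k: int = 3, reps: int = 8, p: int = 300, seed: int = 0,
                        strength: float = 0.6, **overrides) -> SyntheticDesign:
    """Small, fast dataset with clear class signal for pipeline-level tests."""
    overrides.setdefault(
        "class_concentration_means", class_mean_table(k, strength=strength)
    )
    return SyntheticDesign(
        n_classes=k,
        replicates_per_class=reps,
        n_channels=p,
        seed=seed,
        **overrides,
    )


@pytest.fixture
def signal_set():
    """Small raw dataset with strong class structure (3 classes x 8)."""
    return generate_dataset(small_signal_design(seed=1))
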