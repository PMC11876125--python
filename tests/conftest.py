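import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ks_table(rows):
    """Build a valid Ks table from (species, block, a, b, ks[, ka]) tuples."""
    out = []
    for row in rows:
        species, block, a, b, ks = row[:5]
        ka = row[5] if len(row) > 5 else np.nan
        out.append(
            {"species": species, "block_id": block, "gene_a": a,
             "gene_b": b, "ks": float(ks), "ka": ka}
        )
    return pd.DataFrame(
        out, columns=["species", "block_id", "gene_a", "gene_b", "ks", "ka"]
    )


@pytest.fixture()
def ks_table_factory():
    return make_ks_table


@pytest.fixture(scope="session")
def small_dataset():
    """A small, seeded 3+3-species dataset reused by read-only tests."""
    from paleoks.simulate import (
        EventSpec,
        SimConfig,
        SpeciesSpec,
        simulate_ks_dataset,
    )

    species = []
    for i in range(3):
        species.append(
            SpeciesSpec(
                name=f"one_{i}",
                rate_multiplier=1.0 + 0.02 * i,
                events=(EventSpec("ceWGT", 122.5, n_blocks=120),),
                is_reference=(i == 0),
            )
        )
    for i in range(3):
        species.append(
            SpeciesSpec(
                name=f"two_{i}",
                rate_multiplier=1.05 + 0.02 * i,
                events=(
                    EventSpec("ceWGT", 122.5, n_blocks=120),
                    EventSpec("WGD", 45.0, n_blocks=120),
                ),
            )
        )
    return simulate_ks_dataset(SimConfig(species=tuple(species), seed=11))
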