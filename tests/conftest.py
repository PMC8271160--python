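import numpy as np
import pandas as pd
import pytest

from cnr import (
    CopyNumberTable,
    RatioMatrix,
    SimConfig,
    SpeciesRecord,
    simulate_bundle,
)


def make_table(rows, families=None):
    """Build a CopyNumberTable from (id, life_form, total, counts...) tuples."""
    families = families or [f"fam{i + 1}" for i in range(len(rows[0][3]))]
    species = [SpeciesRecord(r[0], r[1], r[2]) for r in rows]
    counts = pd.DataFrame(
        [list(r[3]) for r in rows],
        index=[r[0] for r in rows],
        columns=families,
        dtype=np.int64,
    )
    return CopyNumberTable(species=species, counts=counts)


def make_ratio_matrix(frame: pd.DataFrame, species=None) -> RatioMatrix:
    """Wrap an arbitrary ratio frame (dummy count source for API completeness)."""
    species = species or [
        SpeciesRecord(s, "tree", 1000) for s in frame.index
    ]
    counts = pd.DataFrame(
        0, index=frame.index, columns=frame.columns, dtype=np.int64
    )
    source = CopyNumberTable(species=species, counts=counts)
    return RatioMatrix(ratios=frame, source=source, dropped_families=[])


@pytest.fixture(scope="session")
def small_bundle():
    """A 25-species, 12-family synthetic bundle shared by read-only tests."""
    return simulate_bundle(SimConfig(n_species=25, n_families=12, seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """One study-scale bundle (59 species x 121 families)."""
    return simulate_bundle(SimConfig(seed=11))
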