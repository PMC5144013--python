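import numpy as np
import pandas as pd
import pytest

import microsig as ms


@pytest.fixture
def small_table() -> ms.TaxonTable:
    counts = pd.DataFrame(
        [[2, 2, 4], [5, 0, 0]],
        index=["s1", "s2"], columns=["tA", "tB", "tC"],
    )
    return ms.TaxonTable(counts)


@pytest.fixture
def four_leaf_tree():
    return ms.read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def cohort():
    """Default synthetic two-group cohort with ground truth."""
    cfg = ms.SyntheticConfig(seed=1)
    table, meta, truth = ms.simulate_two_group_tables(cfg)
    return cfg, table, meta, truth


def random_rel_table(rng, n_samples=6, n_taxa=8) -> ms.RelAbundanceTable:
    counts = rng.integers(1, 50, size=(n_samples, n_taxa))
    table = ms.TaxonTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)]))
    return table.to_relative()
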