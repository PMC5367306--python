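import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scallopop.genotypes import GenotypeTable, Locus


def table_from_counts(pop_counts: list[dict[tuple[int, int], int]], kind: str = "snp"):
    """One-locus GenotypeTable from per-population genotype count dicts."""
    rows, labels = [], []
    for p, counts in enumerate(pop_counts):
        for (a, b), c in counts.items():
            rows.extend([[a, b]] * c)
            labels.extend([f"pop{p + 1}"] * c)
    calls = np.asarray(rows)[:, None, :]
    ids = [f"i{k}" for k in range(len(rows))]
    return GenotypeTable(ids, labels, [Locus("L1", kind)], calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20170208)
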