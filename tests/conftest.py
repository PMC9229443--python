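import numpy as np
import pandas as pd
import pytest

from diallelkit import GenotypeTable


def make_table(rows: dict[str, list[str | None]], loci: list[str] | None = None
               ) -> GenotypeTable:
    """Build a GenotypeTable from {line_id: [calls...]}."""
    n = len(next(iter(rows.values())))
    loci = loci or [f"L{j+1}" for j in range(n)]
    calls = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
    calls.columns = loci
    calls.index.name = "line"
    return GenotypeTable(calls)


def random_table(rng: np.random.Generator, n_lines: int = 5, n_loci: int = 6,
                 n_alleles: int = 3, missing_rate: float = 0.0) -> GenotypeTable:
    rows = {}
    for i in range(n_lines):
        calls = []
        for j in range(n_loci):
            if missing_rate and rng.random() < missing_rate:
                calls.append(None)
            else:
                calls.append(f"a{rng.integers(n_alleles)}")
        rows[f"L{i+1}"] = calls
    return make_table(rows, loci=[f"M{j+1}" for j in range(n_loci)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
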