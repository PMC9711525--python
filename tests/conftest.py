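import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import phipkit as pk

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture(scope="session")
def tiny_data():
    return pk.make_fixture("tiny")


@pytest.fixture(scope="session")
def aps1_run():
    """Full aps1_like fixture run through aggregation and enrichment."""
    cm, pmap, sheet, truth = pk.make_fixture("aps1_like")
    gene = pk.aggregate_to_gene(cm, pmap)
    freq = pk.normalize(gene)
    fc = pk.fold_change(freq, sheet)
    z = pk.zscore(fc, sheet)
    return {"gene": gene, "sheet": sheet, "truth": truth,
            "freq": freq, "fc": fc, "z": z}


@pytest.fixture(scope="session")
def null_run():
    cm, pmap, sheet, truth = pk.make_fixture("null")
    gene = pk.aggregate_to_gene(cm, pmap)
    fc = pk.fold_change(pk.normalize(gene), sheet)
    return {"gene": gene, "sheet": sheet, "truth": truth, "fc": fc}


def random_instance(seed: int, n_genes: int = 30, n_cases: int = 20,
                    n_controls: int = 15, n_mock: int = 5):
    """Seeded random counts + sample sheet for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    samples = ([f"case{i}" for i in range(n_cases)]
               + [f"ctrl{i}" for i in range(n_controls)]
               + [f"mock{i}" for i in range(n_mock)])
    roles = dict(zip(samples, ["case"] * n_cases + ["control"] * n_controls
                     + ["mock_ip"] * n_mock))
    counts = pd.DataFrame(
        rng.integers(0, 1000, size=(n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)], columns=samples,
    )
    cm = pk.CountMatrix(counts=counts, level="gene")
    sheet = pk.SampleSheet.from_roles(roles)
    return cm, sheet
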