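import numpy as np
import pandas as pd
import pytest

from phenonet.datatypes import (
    GenotypeMatrix,
    PhenotypeColumn,
    PhenotypeTable,
    Variant,
)


def make_genotypes(dosages, positions=None, chromosome="1", ids=None):
    """Build a GenotypeMatrix from a (n, m) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if ids is None:
        ids = [f"v{j}" for j in range(m)]
    variants = [
        Variant(ids[j], chromosome, int(positions[j]), "A", "G")
        for j in range(m)
    ]
    return GenotypeMatrix([f"ind{i}" for i in range(n)], variants, dosages)


def make_phenotypes(values_dict, kinds=None, categories=None, age=None, sex=None):
    """Build a PhenotypeTable from name -> value-array mapping."""
    names = list(values_dict)
    n = len(next(iter(values_dict.values())))
    kinds = kinds or {}
    categories = categories or {}
    columns = [
        PhenotypeColumn(
            name, kinds.get(name, "continuous"), categories.get(name, "EM")
        )
        for name in names
    ]
    rng = np.random.default_rng(0)
    covariates = pd.DataFrame(
        {
            "age": age if age is not None else rng.integers(30, 70, n).astype(float),
            "sex": sex if sex is not None else (rng.random(n) < 0.5).astype(float),
        }
    )
    return PhenotypeTable(
        [f"ind{i}" for i in range(n)],
        pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values_dict.items()}),
        columns,
        covariates,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes(rng):
    dosages = rng.integers(0, 3, size=(30, 8)).astype(float)
    dosages[3, 2] = np.nan
    return make_genotypes(dosages)
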