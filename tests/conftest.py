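"""Shared fixtures: small deterministic synthetic populations."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from testday import SimConfig, simulate_population
from testday.genotypes import GenotypeMatrix

warnings.filterwarnings("ignore", message="fixed-effect design rank-deficient")


@pytest.fixture(scope="session")
def small_population():
    """~90 animals, 60 herds, 300 SNPs; the workhorse for pipeline tests."""
    cfg = SimConfig(n_herds=60, n_snps=300, seed=42)
    records, genotypes, truth, herds = simulate_population(cfg)
    return {"config": cfg, "records": records, "genotypes": genotypes,
            "truth": truth, "herds": herds}


@pytest.fixture()
def toy_genotypes():
    """Hand-specified 4-animal x 5-SNP matrix with one missing call."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 2, 0, 0],
            [2, 0, 1, 1, 0],
            [0, 2, np.nan, 1, 1],
        ],
        dtype=float,
    )
    return GenotypeMatrix(
        animal_ids=["a1", "a2", "a3", "a4"],
        snp_ids=[f"s{j}" for j in range(5)],
        calls=calls,
        chromosome=np.array(["1", "2", "3", "X", "MT"]),
        position_bp=np.arange(1, 6) * 1000,
    )


def make_records(rows) -> pd.DataFrame:
    """Records table from (animal, herd, cdc, lact, dim, ym, fat) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "herd_id", "cdc_id", "lactation_number",
            "days_in_milk", "year_month", "fat_pct",
        ],
    )


@pytest.fixture()
def records_factory():
    return make_records
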