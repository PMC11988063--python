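"""Worked-example tables from a published smallholder crossbred fat% study.

Small printed summary tables bundled as in-memory fixtures.  They let the
bookkeeping operations (ledger composition, herd-size tabulation, adjusted-
record additivity, heritability arithmetic, GEBV reporting) be exercised
against real published numbers without any data download; none of the model
fitting uses them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ledger import QCLedger, QCLedgerEntry

__all__ = [
    "example_herd_size_counts",
    "example_herd_sizes",
    "example_herd_records",
    "example_geno_qc_ledger",
    "example_pheno_ledger_totals",
    "example_adjusted_components",
    "example_variance_components",
    "example_gebv_values",
]


def example_herd_size_counts() -> pd.DataFrame:
    """Herds per herd-size class (sizes 1-6 and '7 and above')."""
    return pd.DataFrame(
        {
            "herd_size": ["1", "2", "3", "4", "5", "6", "7 and above"],
            "herds": [839, 297, 79, 21, 15, 5, 4],
            "animals": [839, 594, 237, 84, 75, 30, 37],
        }
    )


def example_herd_sizes() -> list[int]:
    """One herd size per herd, consistent with the published composition.

    The open '7 and above' class (4 herds, 37 animals, maximum herd size 14)
    is realized deterministically as sizes 7, 7, 9 and 14.
    """
    sizes = []
    for size, n_herds in zip((1, 2, 3, 4, 5, 6), (839, 297, 79, 21, 15, 5)):
        sizes.extend([size] * n_herds)
    sizes.extend([7, 7, 9, 14])
    return sizes


def example_herd_records() -> pd.DataFrame:
    """A minimal one-record-per-animal table realizing the herd composition."""
    rows = []
    animal = 0
    for h, size in enumerate(example_herd_sizes()):
        for _ in range(size):
            rows.append(
                (f"EX-A{animal:05d}", f"EX-H{h:05d}", "EX-CDC0", 1, 100, "2020-01", 4.5)
            )
            animal += 1
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "herd_id", "cdc_id", "lactation_number",
            "days_in_milk", "year_month", "fat_pct",
        ],
    )


def example_geno_qc_ledger() -> QCLedger:
    """The published genotypic-QC summary as ledger rows.

    Animal stages: 1,478 screened, no duplicates, one animal below the 0.90
    call rate.  SNP stages are both reported against the 49,911 screened
    markers: 4,229 dropped for call rate/MAF, 9,089 dropped as non-autosomal.
    """
    ledger = QCLedger()
    ledger.append(QCLedgerEntry("duplicates", "genotype r > 0.98", 1478, 1478, 0, "animals"))
    ledger.append(QCLedgerEntry("animal_call_rate", "> 0.90", 1478, 1477, 1, "animals"))
    ledger.append(
        QCLedgerEntry(
            "snp_call_rate_and_maf", "call rate > 0.95 and MAF > 0.01",
            49_911, 45_682, 4_229, "snps",
        )
    )
    ledger.append(
        QCLedgerEntry(
            "autosomes_only", "removal of X, Y, MT markers",
            49_911, 40_822, 9_089, "snps",
        )
    )
    return ledger


def example_pheno_ledger_totals() -> QCLedgerEntry:
    """Phenotypic QC totals: 45,978 raw records, 33,845 retained."""
    return QCLedgerEntry(
        "phenotypic_qc_total", "3-step sequential QC", 45_978, 33_845, 12_133, "records"
    )


def example_adjusted_components() -> pd.DataFrame:
    """Published adjusted-record components (IFE, ARE, HRE) for ten records.

    The AFP column is recomputed as IFE + ARE + HRE by the stage-1
    operations; the published print shows the same values up to +/-0.01
    rounding.
    """
    data = [
        ("EX-COW-1", 0.13, -0.05, 0.05),
        ("EX-COW-1", -0.10, -0.05, 0.05),
        ("EX-COW-1", 0.44, -0.05, 0.05),
        ("EX-COW-1", 0.49, -0.05, 0.05),
        ("EX-COW-2", -0.33, 0.30, 0.05),
        ("EX-COW-2", 0.44, 0.30, 0.05),
        ("EX-COW-1", 0.87, -0.05, 0.05),
        ("EX-COW-1", -0.84, -0.05, 0.05),
        ("EX-COW-2", -0.30, 0.30, 0.05),
        ("EX-COW-1", 0.28, -0.05, 0.05),
    ]
    return pd.DataFrame(data, columns=["animal_id", "ife", "are", "hre"])


def example_variance_components() -> dict:
    """Published variance components for milk fat% (fat%^2)."""
    return {"Va": 0.012, "Ve": 0.106, "Vp": 0.118}


def example_gebv_values() -> np.ndarray:
    """The 25 published GEBV values (%) for milk fat percentage."""
    return np.array(
        [
            3.10, 2.77, 2.44, 2.32, 2.21, 1.63, 1.63, 1.14, 1.11, 1.07,
            1.05, 1.05, 1.00, 0.97, 0.95, 0.22, 0.21, 0.13, 0.12, 0.22,
            -0.095, -0.096, -0.096, -0.096, -0.096,
        ]
    )
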