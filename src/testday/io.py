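"""File formats: phenotype CSV, PLINK-style PED/MAP text genotypes, ledgers,
GRM tables, posterior summaries and GEBV reports.

Conventions: UTF-8 throughout; comma-separated data files, tab-separated
ledgers and reports; decimal points, no thousands separators.  Output
artifacts embed the pipeline configuration hash and seed as ``#`` comment
headers for provenance; readers skip such lines.  Animal identifiers are
opaque strings and are never parsed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grm import GRMatrix
from .simulate import PHENOTYPE_COLUMNS

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "write_grm",
    "write_gebv_table",
    "write_posterior_json",
    "plot_fat_histograms",
]

logger = logging.getLogger(__name__)

_NUMERIC = {"lactation_number": int, "days_in_milk": int, "fat_pct": float}


def _provenance_header(config_hash: str | None, seed: int | None) -> str:
    parts = ["# testday"]
    if config_hash:
        parts.append(f"config={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts) + "\n"


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Typed test-day records plus a reject report for malformed rows.

    Rows with unparseable numeric fields are collected (with a reason) into
    the second returned frame rather than silently dropped.  Missing
    required columns raise.
    """
    raw = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype file {path} is missing columns: {missing}")
    work = raw.copy()
    reasons = pd.Series("", index=work.index)
    for col, typ in _NUMERIC.items():
        coerced = pd.to_numeric(work[col], errors="coerce")
        bad = coerced.isna() & work[col].notna()
        reasons[bad] += f"unparseable {col};"
        work[col] = coerced
    empty = work[list(PHENOTYPE_COLUMNS)].isna().any(axis=1)
    reasons[empty & (reasons == "")] = "missing value;"
    ok = reasons == ""
    records = work[ok].copy()
    for col, typ in _NUMERIC.items():
        records[col] = records[col].astype(typ)
    rejects = raw[~ok].copy()
    rejects["reason"] = reasons[~ok]
    if len(rejects):
        logger.warning("rejected %d malformed phenotype rows", len(rejects))
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def write_phenotypes(records: pd.DataFrame, path, config_hash: str | None = None,
                     seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config_hash, seed))
        records.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def write_genotypes(matrix: GenotypeMatrix, prefix) -> None:
    """Write a PED/MAP pair; alleles coded A (reference) / B (alternate).

    Dosage 0 -> "A A", 1 -> "A B", 2 -> "B B", missing -> "0 0".  The MAP
    file carries chromosome, SNP id, 0 cM, position.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(matrix.n_snps):
            fh.write(
                f"{matrix.chromosome[j]}\t{matrix.snp_ids[j]}\t0\t{matrix.position_bp[j]}\n"
            )
    coding = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(matrix.animal_ids):
            fields = [aid, aid, "0", "0", "0", "-9"]
            row = matrix.calls[i]
            fields.extend(
                "0 0" if np.isnan(v) else coding[float(v)] for v in row
            )
            fh.write("\t".join(fields) + "\n")


def read_genotypes(prefix) -> GenotypeMatrix:
    """Read a PED/MAP pair into 0/1/2 dosages of the per-SNP counted allele.

    For A/B-coded files the counted allele is B.  Otherwise the counted
    allele is the lexicographically later of the two alleles observed at the
    SNP (a deterministic convention; flip dosages downstream if a specific
    strand/allele orientation is needed).  "0" allele codes are missing.
    """
    prefix = Path(prefix)
    map_rows = []
    with open(prefix.with_suffix(".map")) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"malformed MAP line: {line!r}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    animal_ids, genotype_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            animal_ids.append(parts[1])
            genotype_rows.append(parts[6:])

    calls = np.full((len(animal_ids), m), np.nan)
    pairs = np.array(genotype_rows, dtype=object).reshape(len(animal_ids), m, 2) \
        if animal_ids else np.empty((0, m, 2), dtype=object)
    for j in range(m):
        col = pairs[:, j, :]
        alleles = sorted(set(col.ravel()) - {"0"})
        if not alleles:
            continue  # all-missing SNP stays nan
        if len(alleles) > 2:
            raise ValueError(f"SNP {map_rows[j][1]} has >2 alleles: {alleles}")
        counted = "B" if alleles == ["A", "B"] or alleles == ["B"] else alleles[-1]
        obs = ~np.any(col == "0", axis=1)
        calls[obs, j] = (col[obs] == counted).sum(axis=1)
    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=[r[1] for r in map_rows],
        calls=calls,
        chromosome=np.array([r[0] for r in map_rows]),
        position_bp=np.array([r[2] for r in map_rows], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

def write_grm(G: GRMatrix, path, triplet_path=None, config_hash=None, seed=None) -> None:
    """Symmetric full-matrix TSV; optionally a sparse (i, j, value) triplet
    table with a 0-based animal-id index column order."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(config_hash, seed))
        G.to_frame().to_csv(fh, sep="\t")
    if triplet_path is not None:
        n = G.n_animals
        ii, jj = np.tril_indices(n)
        trip = pd.DataFrame({"i": ii, "j": jj, "value": G.values[ii, jj]})
        with open(triplet_path, "w") as fh:
            fh.write(_provenance_header(config_hash, seed))
            fh.write("# index: " + ",".join(G.animal_ids) + "\n")
            trip.to_csv(fh, sep="\t", index=False)


def write_gebv_table(table: pd.DataFrame, path, config_hash=None, seed=None) -> None:
    out = table.rename(columns={"animal_id": "AnimalID", "gebv": "GEBV(%)"})
    with open(path, "w") as fh:
        fh.write(_provenance_header(config_hash, seed))
        out.to_csv(fh, sep="\t", index=False)


def write_posterior_json(summary, path, config_hash=None, seed=None) -> None:
    payload = {
        "engine": summary.engine,
        "n_chains": summary.config.n_chains,
        "n_retained_per_chain": summary.n_retained_per_chain,
        "provenance": {"config": config_hash, "seed": seed},
        "parameters": {},
    }
    for name in summary.scalar_names():
        lo, hi = summary.credible_interval(name)
        payload["parameters"][name] = {
            "mean": summary.mean(name),
            "sd": summary.sd(name),
            "ci90": [lo, hi],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plot_fat_histograms(before: pd.DataFrame, after: pd.DataFrame, path) -> None:
    """Before/after QC fat% histograms (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, frame, title in ((axes[0], before, "before QC"), (axes[1], after, "after QC")):
        ax.hist(frame["fat_pct"], bins=40, color="tab:blue", alpha=0.8)
        ax.set_xlabel("fat %")
        ax.set_title(title)
    axes[0].set_ylabel("records")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
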