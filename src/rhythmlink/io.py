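"""Readers and writers for the flat-file formats the pipeline consumes.

Cohorts travel as TSV with a YAML sidecar of measure metadata; genotype
dosages as a PLINK ``.raw``-style export or plain TSV; polygenic weight
tables as 6-column CHR/SNP/BP/A1/A2/BETA TSV (PRS-CS output layout);
GWAS summary statistics as SNP/A1/A2/FRQ/BETA/SE/N TSV.  Column names
can be remapped for files from other tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sem import Cell, FactorModelSpec
from .simulate import CohortTable, GenotypeMatrix

SUMSTATS_COLS = ["SNP", "A1", "A2", "FRQ", "BETA", "SE", "N"]
WEIGHT_COLS = ["CHR", "SNP", "BP", "A1", "A2", "BETA"]


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------
def write_cohort(cohort: CohortTable, tsv_path: str | Path,
                 yaml_path: str | Path | None = None) -> None:
    tsv_path = Path(tsv_path)
    cohort.data.to_csv(tsv_path, sep="\t", index=True, na_rep="NA")
    meta_path = Path(yaml_path) if yaml_path else tsv_path.with_suffix(".yaml")
    meta = {m: {k: (bool(v) if isinstance(v, (bool, np.bool_)) else
                    float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in row.items()}
            for m, row in cohort.metadata.to_dict("index").items()}
    with open(meta_path, "w") as fh:
        yaml.safe_dump({"measures": meta}, fh, sort_keys=False)


def read_cohort(tsv_path: str | Path,
                yaml_path: str | Path | None = None) -> CohortTable:
    tsv_path = Path(tsv_path)
    data = pd.read_csv(tsv_path, sep="\t", index_col="individual_id",
                       na_values=["NA"])
    meta_path = Path(yaml_path) if yaml_path else tsv_path.with_suffix(".yaml")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)["measures"]
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    metadata.index.name = "measure"
    return CohortTable(data=data, metadata=metadata)


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def write_genotypes_raw(geno: GenotypeMatrix, path: str | Path) -> None:
    """PLINK ``.raw`` dialect: FID IID PAT MAT SEX PHENOTYPE <SNP>_<A1>."""
    cols = {"FID": geno.dosages.index, "IID": geno.dosages.index,
            "PAT": 0, "MAT": 0, "SEX": 0, "PHENOTYPE": -9}
    for snp in geno.dosages.columns:
        a1 = geno.snps.loc[snp, "effect_allele"]
        cols[f"{snp}_{a1}"] = geno.dosages[snp].to_numpy()
    pd.DataFrame(cols).to_csv(path, sep=" ", index=False, na_rep="NA")


def read_genotypes_raw(path: str | Path,
                       snps: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a ``.raw`` export; allele parsed from the ``SNP_A1`` headers.

    Without a ``snps`` table the other allele is unknown ('N') and MAF is
    estimated from the dosages.
    """
    raw = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in raw.columns if c not in meta_cols]
    ids, a1s, dose = [], [], {}
    for c in snp_cols:
        snp_id, _, a1 = c.rpartition("_")
        ids.append(snp_id)
        a1s.append(a1)
        dose[snp_id] = raw[c].to_numpy(dtype=float)
    dosages = pd.DataFrame(dose)
    dosages.index = pd.Index(raw["IID"], name="individual_id")
    if snps is None:
        freq = np.nanmean(dosages.to_numpy(), axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        snps = pd.DataFrame({
            "chr": 0, "bp": 0, "effect_allele": a1s, "other_allele": "N",
            "maf": maf,
        }, index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(dosages=dosages, snps=snps)


# ----------------------------------------------------------------------
# weights / summary statistics
# ----------------------------------------------------------------------
def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights[WEIGHT_COLS].to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path,
                 column_map: dict[str, str] | None = None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if column_map:
        tab = tab.rename(columns=column_map)
    missing = [c for c in WEIGHT_COLS if c not in tab.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    return tab[WEIGHT_COLS]


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    ss[SUMSTATS_COLS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path,
                  column_map: dict[str, str] | None = None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    if column_map:
        tab = tab.rename(columns=column_map)
    missing = [c for c in SUMSTATS_COLS if c not in tab.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    return tab[SUMSTATS_COLS]


# ----------------------------------------------------------------------
# model specs
# ----------------------------------------------------------------------
def spec_to_yaml(spec: FactorModelSpec, path: str | Path) -> None:
    doc = {
        "observed": list(spec.observed),
        "factors": list(spec.factors),
        "exogenous": list(spec.exogenous),
        "defined": dict(spec.defined),
        "cells": [
            {"matrix": c.matrix, "row": c.row, "col": c.col,
             "free": bool(c.free), "value": float(c.value),
             "label": c.label, "expr": c.expr}
            for c in spec.cells
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path: str | Path) -> FactorModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cells = [Cell(**c) for c in doc["cells"]]
    return FactorModelSpec(
        observed=doc["observed"], factors=doc["factors"], cells=cells,
        exogenous=doc.get("exogenous", []), defined=doc.get("defined", {}),
    )
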