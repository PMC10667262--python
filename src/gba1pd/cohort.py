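"""Cohort table schema and TSV round-tripping.

A cohort is a pandas DataFrame with one row per participant.  Core columns:

==========================  ====================================================
column                      meaning
==========================  ====================================================
id                          participant identifier (unique)
family_id                   family cluster identifier
group                       PD, PSP, DLB, MSA, FTDP or HC
sex                         "M" / "F"
aao                         age at disease onset, years (patients; NaN for HC)
aaa                         age at assessment, years
disease_duration            aaa - aao, years (patients)
pc1, pc2                    ancestry principal components
first_degree_pd_relative    has a first-degree relative with PD
other_gene_pathogenic       pathogenic point mutation in another PD gene
cnv_carrier                 CNV in a PD gene
family_history              reported family history of PD
carrier_class               none / severe / mild / risk / vus / synonymous
variants                    semicolon-joined variant names carried
==========================  ====================================================

Clinical outcome columns (continuous scales, 0/1 symptoms) follow; missing
measurements are NaN.  Booleans are stored as 0/1 integers so the table
survives a TSV round trip unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

PATIENT_GROUPS = ("PD", "PSP", "DLB", "MSA", "FTDP")
GROUPS = PATIENT_GROUPS + ("HC",)

CARRIER_CLASSES = ("none", "severe", "mild", "risk", "vus", "synonymous")
PATHOGENIC_CLASSES = ("severe", "mild", "risk")
# "any GBA1 carrier" in the frequency tables counts non-synonymous classes only
ANY_CARRIER_CLASSES = ("severe", "mild", "risk", "vus")

CORE_COLUMNS = [
    "id",
    "family_id",
    "group",
    "sex",
    "aao",
    "aaa",
    "disease_duration",
    "pc1",
    "pc2",
    "first_degree_pd_relative",
    "other_gene_pathogenic",
    "cnv_carrier",
    "family_history",
    "carrier_class",
    "variants",
]

FLAG_COLUMNS = [
    "first_degree_pd_relative",
    "other_gene_pathogenic",
    "cnv_carrier",
    "family_history",
]


def is_patient(cohort: pd.DataFrame) -> pd.Series:
    return cohort["group"].isin(PATIENT_GROUPS)


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the core schema; raises ValueError on violations."""
    missing = [c for c in CORE_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing columns: {missing}")
    if cohort["id"].duplicated().any():
        dups = cohort.loc[cohort["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dups[:5]}")
    bad = set(cohort["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups: {sorted(bad)}")
    bad = set(cohort["carrier_class"]) - set(CARRIER_CLASSES)
    if bad:
        raise ValueError(f"unknown carrier classes: {sorted(bad)}")


def write_cohort(cohort: pd.DataFrame, path: Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort(path: Path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"id": str, "family_id": str})
    cohort["variants"] = cohort["variants"].fillna("")
    for col in FLAG_COLUMNS:
        cohort[col] = cohort[col].fillna(0).astype(np.int64)
    validate_cohort(cohort)
    return cohort
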