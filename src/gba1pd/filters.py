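"""The cohort exclusion cascade, with a conserving audit trail.

Four steps, applied in the order the study narrative reports them:

1. remove carriers of pathogenic point mutations or CNVs in other
   Parkinson's-disease genes;
2. keep one proband per family (among cases, the earliest age at onset);
3. remove healthy controls younger than 60 at assessment who have a
   first-degree relative with PD (age-dependent penetrance guard);
4. remove ancestry outliers beyond 3 SD on either of the first two
   principal components.

Each step records who it removed; the audit conserves counts at every step
and the full cascade is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gba1pd.cohort import is_patient

__all__ = [
    "ExclusionAudit",
    "exclude_flag_carriers",
    "select_probands",
    "exclude_young_related_hc",
    "ancestry_outliers",
    "run_exclusion_cascade",
]


@dataclass
class ExclusionStep:
    rule: str
    n_excluded: int
    excluded_ids: tuple[str, ...]
    n_remaining: int


@dataclass
class ExclusionAudit:
    n_input: int
    steps: list[ExclusionStep] = field(default_factory=list)

    def record(self, rule: str, excluded_ids: list[str], n_remaining: int) -> None:
        self.steps.append(
            ExclusionStep(rule, len(excluded_ids), tuple(sorted(excluded_ids)), n_remaining)
        )

    @property
    def n_remaining(self) -> int:
        return self.steps[-1].n_remaining if self.steps else self.n_input

    def is_conserving(self) -> bool:
        return self.n_input - sum(s.n_excluded for s in self.steps) == self.n_remaining

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rule": s.rule,
                    "n_excluded": s.n_excluded,
                    "n_remaining": s.n_remaining,
                    "excluded_ids": ";".join(s.excluded_ids),
                }
                for s in self.steps
            ]
        )


def exclude_flag_carriers(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop carriers of other-PD-gene point mutations or CNVs."""
    mask = (cohort["other_gene_pathogenic"].astype(bool)) | (
        cohort["cnv_carrier"].astype(bool)
    )
    removed = cohort.loc[mask, "id"].tolist()
    return cohort.loc[~mask].copy(), removed


def select_probands(cohort: pd.DataFrame, prefer_case: bool = True) -> tuple[pd.DataFrame, list[str]]:
    """Keep one proband per family.

    Among case members the earliest age at onset wins (ties by smallest id);
    families with only controls keep the smallest id.  When ``prefer_case``
    is False a mixed family keeps its smallest-id member regardless of
    diagnosis.
    """
    keep: list[int] = []
    removed: list[str] = []
    patient = is_patient(cohort)
    for _, members in cohort.groupby("family_id", sort=False):
        if len(members) == 1:
            keep.extend(members.index)
            continue
        cases = members.loc[patient.loc[members.index]]
        if prefer_case and len(cases):
            aao = cases["aao"].fillna(np.inf)
            chosen = cases.loc[aao == aao.min(), "id"].sort_values().index[0]
        else:
            chosen = members["id"].sort_values().index[0]
        keep.append(chosen)
        removed.extend(members.loc[members.index != chosen, "id"])
    kept = cohort.loc[cohort.index.isin(set(keep))].copy()
    return kept, removed


def exclude_young_related_hc(cohort: pd.DataFrame, aaa_threshold: float = 60.0) -> tuple[pd.DataFrame, list[str]]:
    """Drop HC with a first-degree PD relative assessed before ``aaa_threshold``."""
    mask = (
        (cohort["group"] == "HC")
        & cohort["first_degree_pd_relative"].astype(bool)
        & (cohort["aaa"] < aaa_threshold)
    )
    removed = cohort.loc[mask, "id"].tolist()
    return cohort.loc[~mask].copy(), removed


def ancestry_outliers(pcs: pd.DataFrame, n_sd: float = 3.0) -> set[str]:
    """Flag ids beyond ``n_sd`` standard deviations on PC1 or PC2.

    Mean and SD are computed once on the supplied table.  A component with
    zero variance yields no outliers (with a warning) rather than dividing
    by zero.
    """
    if len(pcs) < 3:
        raise ValueError("ancestry outlier detection needs at least 3 participants")
    if not np.isfinite(pcs[["pc1", "pc2"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite principal components")
    flagged: set[str] = set()
    for col in ("pc1", "pc2"):
        values = pcs[col].to_numpy(dtype=float)
        sd = values.std(ddof=1)
        if sd == 0.0:
            warnings.warn(f"zero variance on {col}; no outliers flagged", stacklevel=2)
            continue
        mask = np.abs(values - values.mean()) > n_sd * sd
        flagged.update(pcs.loc[mask, "id"])
    return flagged


def run_exclusion_cascade(
    cohort: pd.DataFrame,
    aaa_threshold: float = 60.0,
    n_sd: float = 3.0,
    prefer_case: bool = True,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply all four exclusion steps in order and return the audit."""
    audit = ExclusionAudit(n_input=len(cohort))
    if cohort.empty:
        return cohort.copy(), audit

    cohort, removed = exclude_flag_carriers(cohort)
    audit.record("other_gene_or_cnv_carrier", removed, len(cohort))

    cohort, removed = select_probands(cohort, prefer_case=prefer_case)
    audit.record("one_proband_per_family", removed, len(cohort))

    cohort, removed = exclude_young_related_hc(cohort, aaa_threshold=aaa_threshold)
    audit.record("young_hc_with_pd_relative", removed, len(cohort))

    outliers = ancestry_outliers(cohort[["id", "pc1", "pc2"]], n_sd=n_sd)
    cohort2 = cohort.loc[~cohort["id"].isin(outliers)].copy()
    audit.record("ancestry_outlier", sorted(outliers), len(cohort2))

    assert audit.is_conserving()
    return cohort2, audit
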