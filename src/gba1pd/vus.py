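"""Rule-based pathogenicity triage for GBA1 variants of unknown significance.

Each VUS is judged from three evidence channels: who carries it (patients
vs healthy controls, and whether any carrier had early-onset disease, AAO
<= 45), what the in-silico predictors say (REVEL/CADD deleterious-vs-
tolerated calls for missense, dbscSNV ada/rf splice scores for splice-region
variants), and database labels (HGMD, ClinVar).  The base rules:

1. patients-only and every present score deleterious, or any early-onset
   patient carrier -> probably severe;
2. carriers in both patients and controls, or disagreeing score calls, or an
   HGMD "PD susceptibility" label -> probably risk;
3. patients-only and every present score tolerated -> probably mild;
4. controls-only -> probably benign.

Disagreeing calls take precedence over the tolerated-consensus mild rule.
Structural proximity to a known pathogenic variant is appended as supporting
evidence; an opt-in override downgrades a tolerated-consensus variant sitting
in an isolated coil with no proximity hits to probably benign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreAnnotation",
    "CarrierContext",
    "Verdict",
    "ProposedClass",
    "ZScoreResult",
    "UnclassifiableVariantError",
    "splice_affects",
    "propose_class",
    "classify_vus_table",
    "carrier_zscore",
]

SPLICE_SCORE_THRESHOLD = 0.6
EARLY_ONSET_AAO = 45.0
# numeric fallbacks when only raw scores are available; the study itself
# works from categorical D/T calls, so these are a documented extrapolation
REVEL_DELETERIOUS = 0.5
CADD_PHRED_DELETERIOUS = 20.0


@dataclass
class ScoreAnnotation:
    """In-silico evidence bundle for one variant."""

    revel: Optional[float] = None
    revel_call: Optional[str] = None
    cadd_phred: Optional[float] = None
    cadd_call: Optional[str] = None
    ada_score: Optional[float] = None
    rf_score: Optional[float] = None
    hgmd_label: Optional[str] = None
    clinvar_label: Optional[str] = None

    def __post_init__(self) -> None:
        for call in (self.revel_call, self.cadd_call):
            if call is not None and call not in ("D", "T"):
                raise ValueError(f"score call must be 'D' or 'T', got {call!r}")
        if all(
            v is None
            for v in (
                self.revel, self.revel_call, self.cadd_phred, self.cadd_call,
                self.ada_score, self.rf_score, self.hgmd_label, self.clinvar_label,
            )
        ):
            raise ValueError("score annotation with no evidence at all")

    def predictor_calls(self, is_splice: bool = False) -> list[str]:
        """Categorical D/T calls from the numeric predictors present."""
        calls: list[str] = []
        if self.revel_call is not None:
            calls.append(self.revel_call)
        elif self.revel is not None:
            calls.append("D" if self.revel >= REVEL_DELETERIOUS else "T")
        if self.cadd_call is not None:
            calls.append(self.cadd_call)
        elif self.cadd_phred is not None:
            calls.append("D" if self.cadd_phred >= CADD_PHRED_DELETERIOUS else "T")
        if is_splice and (self.ada_score is not None or self.rf_score is not None):
            calls.append("D" if splice_affects(self.ada_score, self.rf_score) else "T")
        return calls


@dataclass
class CarrierContext:
    """Who carries the variant in the study cohort."""

    n_patient_carriers: int
    n_hc_carriers: int
    any_early_onset_patient: bool = False

    def __post_init__(self) -> None:
        if self.n_patient_carriers < 0 or self.n_hc_carriers < 0:
            raise ValueError("carrier counts must be >= 0")


class Verdict(Enum):
    PROBABLY_SEVERE = "probably_severe"
    PROBABLY_MILD = "probably_mild"
    PROBABLY_RISK = "probably_risk"
    PROBABLY_BENIGN = "probably_benign"


@dataclass
class ProposedClass:
    verdict: Verdict
    rationale: list[str]
    structural_evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("a verdict needs a non-empty rationale")


class UnclassifiableVariantError(ValueError):
    """No triage rule fires (e.g. no carriers, or no usable evidence)."""


def splice_affects(ada_score: Optional[float], rf_score: Optional[float]) -> bool:
    """dbscSNV splice-impact flag: either present score >= 0.6."""
    if ada_score is None and rf_score is None:
        raise ValueError("splice_affects needs at least one dbscSNV score")
    for score in (ada_score, rf_score):
        if score is not None and score >= SPLICE_SCORE_THRESHOLD:
            return True
    return False


def propose_class(
    hgvs_p: str,
    scores: ScoreAnnotation,
    context: CarrierContext,
    structural_hits: Optional[Sequence] = None,
    secondary_structure: Optional[str] = None,
    is_splice: bool = False,
    allow_benign_override: bool = False,
) -> ProposedClass:
    """Apply the triage rules to one VUS.

    ``structural_hits`` are :class:`gba1pd.structure.ProximityHit` findings
    for this variant; they never change the base verdict unless the opt-in
    benign override applies (tolerated consensus, isolated coil, no hits).
    """
    hits = list(structural_hits or [])
    calls = scores.predictor_calls(is_splice=is_splice)
    all_deleterious = bool(calls) and all(c == "D" for c in calls)
    all_tolerated = bool(calls) and all(c == "T" for c in calls)
    mixed = ("D" in calls) and ("T" in calls)
    patients_only = context.n_patient_carriers > 0 and context.n_hc_carriers == 0
    hc_only = context.n_hc_carriers > 0 and context.n_patient_carriers == 0
    in_both = context.n_patient_carriers > 0 and context.n_hc_carriers > 0
    pd_susceptibility = (scores.hgmd_label or "").strip().lower() == "pd susceptibility"

    rationale: list[str] = []
    verdict: Optional[Verdict] = None
    if patients_only and (all_deleterious or context.any_early_onset_patient):
        verdict = Verdict.PROBABLY_SEVERE
        rationale.append("carriers_patients_only")
        if all_deleterious:
            rationale.append("all_scores_deleterious")
        if context.any_early_onset_patient:
            rationale.append("early_onset_patient_carrier")
    elif in_both or mixed or pd_susceptibility:
        verdict = Verdict.PROBABLY_RISK
        if in_both:
            rationale.append("carriers_in_patients_and_controls")
        if mixed:
            rationale.append("score_calls_disagree")
        if pd_susceptibility:
            rationale.append("hgmd_pd_susceptibility")
    elif patients_only and all_tolerated:
        verdict = Verdict.PROBABLY_MILD
        rationale.extend(["carriers_patients_only", "all_scores_tolerated"])
    elif hc_only:
        verdict = Verdict.PROBABLY_BENIGN
        rationale.append("carriers_controls_only")

    if verdict is None:
        raise UnclassifiableVariantError(
            f"{hgvs_p}: no triage rule fires "
            f"(patients={context.n_patient_carriers}, hc={context.n_hc_carriers}, "
            f"calls={calls})"
        )

    for hit in hits:
        rationale.append(f"proximal_to_known_pathogenic:{_hit_label(hit)}")
    if (
        allow_benign_override
        and verdict is Verdict.PROBABLY_MILD
        and all_tolerated
        and not hits
        and (secondary_structure or "").lower() == "coil"
    ):
        verdict = Verdict.PROBABLY_BENIGN
        rationale.append("structural_benign_override:isolated_coil_no_proximity")

    return ProposedClass(verdict=verdict, rationale=rationale, structural_evidence=hits)


def _hit_label(hit) -> str:
    neighbor = getattr(hit, "neighbor_hgvs_p", None)
    return str(neighbor if neighbor is not None else hit)


def classify_vus_table(
    table: pd.DataFrame,
    structural_hits: Optional[dict[str, Sequence]] = None,
    allow_benign_override: bool = False,
    early_onset_threshold: float = EARLY_ONSET_AAO,
) -> pd.DataFrame:
    """Run the triage engine over an annotation table (one row per VUS).

    Expects the columns of ``data/vus_annotations.tsv``.  Returns the table
    with ``verdict`` and ``rationale`` columns appended.
    """
    structural_hits = structural_hits or {}
    verdicts, rationales = [], []
    for _, row in table.iterrows():
        scores = ScoreAnnotation(
            revel_call=_opt_str(row.get("revel_call")),
            cadd_call=_opt_str(row.get("cadd_call")),
            ada_score=_opt_float(row.get("ada_score")),
            rf_score=_opt_float(row.get("rf_score")),
            hgmd_label=_opt_str(row.get("hgmd_label")),
            clinvar_label=_opt_str(row.get("clinvar_label")),
        )
        aao = _opt_float(row.get("min_carrier_aao"))
        context = CarrierContext(
            n_patient_carriers=int(row["n_patient_carriers"]),
            n_hc_carriers=int(row["n_hc_carriers"]),
            any_early_onset_patient=aao is not None and aao <= early_onset_threshold,
        )
        proposed = propose_class(
            row["hgvs_p"],
            scores,
            context,
            structural_hits=structural_hits.get(row["hgvs_p"]),
            secondary_structure=_opt_str(row.get("secondary_structure")),
            is_splice=row.get("consequence") == "splice_region",
            allow_benign_override=allow_benign_override,
        )
        verdicts.append(proposed.verdict.value)
        rationales.append(";".join(proposed.rationale))
    out = table.copy()
    out["verdict"] = verdicts
    out["rationale"] = rationales
    return out


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)


def _opt_float(value) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


@dataclass
class ZScoreResult:
    value: float
    reference_mean: float
    reference_sd: float

    @property
    def z(self) -> float:
        return (self.value - self.reference_mean) / self.reference_sd


def carrier_zscore(
    x: float,
    reference_values: Optional[Sequence[float]] = None,
    *,
    mean: Optional[float] = None,
    sd: Optional[float] = None,
) -> ZScoreResult:
    """Standardize one carrier's clinical score against a reference group.

    Either pass the reference group's raw values (sample mean and SD,
    ddof=1, are used) or a published mean and SD directly.
    """
    if reference_values is not None:
        values = np.asarray(reference_values, dtype=float)
        if values.size < 2:
            raise ValueError("reference group must have at least 2 values")
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
    if mean is None or sd is None:
        raise ValueError("need reference_values or both mean and sd")
    if sd <= 0:
        raise ValueError("reference SD must be positive")
    return ZScoreResult(value=float(x), reference_mean=mean, reference_sd=sd)
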