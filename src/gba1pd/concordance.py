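"""Callset filtering and concordance against a Sanger-validated gold standard.

The unit of comparison is the *carrier event*: one (sample, variant) pair, or
one (sample, named recombinant allele) pair after collapsing phased
components.  A RecNciI carrier therefore counts once whether a platform
reports the named allele or its three component variants.

TPR = TP / (TP + FN) over gold-standard events; callset FDR = FP / (TP + FP).
Formatted rates follow the truncation convention of
:mod:`gba1pd.formatting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from gba1pd.formatting import trunc_pct
from gba1pd.variants import GbaVariant, KnownVariantCatalog, collapse_carrier_events

__all__ = [
    "CallRecord",
    "GoldStandard",
    "FilterConfig",
    "ConcordanceResult",
    "filter_callset",
    "calls_to_events",
    "evaluate_concordance",
    "compare_methods",
]

Event = tuple[str, str]  # (sample_id, variant or complex-allele name)


@dataclass
class CallRecord:
    """One platform's call of one variant in one sample."""

    sample_id: str
    variant: GbaVariant
    platform: str = ""
    chrom: Optional[str] = None
    pos: Optional[int] = None

    @property
    def qual(self) -> Optional[float]:
        return self.variant.qual


@dataclass(frozen=True)
class GoldStandard:
    """Sanger-validated carrier events."""

    validated: frozenset[Event]

    @classmethod
    def from_pairs(cls, pairs: Iterable[Event]) -> "GoldStandard":
        pairs = list(pairs)
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate carrier events in gold standard")
        return cls(validated=frozenset(pairs))

    def __len__(self) -> int:
        return len(self.validated)


@dataclass
class FilterConfig:
    """Quality / rarity predicates applied before scoring a callset.

    Calls must have QUAL strictly above ``qual_min``, gnomAD non-Finnish
    European MAF strictly below ``maf_nfe_max``, a within-study carrier
    frequency strictly below ``study_freq_max``, and (when coordinates are
    present) fall inside ``region``.
    """

    qual_min: float = 30.0
    maf_nfe_max: float = 0.01
    study_freq_max: float = 0.01
    region: Optional[tuple[str, int, int]] = ("chr1", 155_232_501, 155_241_415)
    genotyping_rate_min: float = 0.95
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("qual_min", "maf_nfe_max", "study_freq_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class MissingAnnotationError(ValueError):
    """A call record lacks a field a filter predicate needs."""


def filter_callset(
    records: Sequence[CallRecord],
    config: FilterConfig,
    n_samples: Optional[int] = None,
) -> tuple[list[CallRecord], dict[str, int]]:
    """Apply the quality/rarity predicates, preserving input order.

    Returns the surviving records and an audit mapping predicate name to the
    number of records it removed (a record failing several predicates is
    charged to the first, in the order qual, maf, study frequency, region).
    """
    if n_samples is None:
        n_samples = len({r.sample_id for r in records})
    counts: dict[str, int] = {}
    for r in records:
        key = r.variant.key
        counts[key] = counts.get(key, 0) + 1

    audit = {"qual": 0, "maf_nfe": 0, "study_freq": 0, "region": 0}
    kept: list[CallRecord] = []
    for r in records:
        if r.variant.qual is None:
            raise MissingAnnotationError(f"record {r.sample_id}/{r.variant.key}: missing qual")
        if r.variant.maf_nfe is None:
            raise MissingAnnotationError(
                f"record {r.sample_id}/{r.variant.key}: missing maf_nfe"
            )
        if not r.variant.qual > config.qual_min:
            audit["qual"] += 1
            continue
        if not r.variant.maf_nfe < config.maf_nfe_max:
            audit["maf_nfe"] += 1
            continue
        study_freq = counts[r.variant.key] / n_samples if n_samples else 0.0
        if not study_freq < config.study_freq_max:
            audit["study_freq"] += 1
            continue
        if config.region is not None and r.pos is not None:
            chrom, start, end = config.region
            if r.chrom != chrom or not start <= r.pos <= end:
                audit["region"] += 1
                continue
        kept.append(r)
    return kept, audit


def calls_to_events(
    records: Iterable[CallRecord], catalog: KnownVariantCatalog
) -> set[Event]:
    """Deduplicate calls and collapse phased complex-allele components."""
    by_sample: dict[str, list[GbaVariant]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r.variant)
    events: set[Event] = set()
    for sample, variants in by_sample.items():
        # drop exact duplicates before collapsing
        seen: dict[str, GbaVariant] = {}
        for v in variants:
            seen.setdefault(v.key, v)
        for name in collapse_carrier_events(list(seen.values()), catalog):
            events.add((sample, name))
    return events


@dataclass
class ConcordanceResult:
    """TP/FP/FN bookkeeping for one platform against the gold standard."""

    tp: int
    fp: int
    fn: int
    breakdown: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def tpr(self) -> Optional[float]:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def fdr(self) -> Optional[float]:
        denom = self.tp + self.fp
        return self.fp / denom if denom else None

    @property
    def tpr_formatted(self) -> str:
        return trunc_pct(self.tpr)

    @property
    def fdr_formatted(self) -> str:
        return trunc_pct(self.fdr)


def evaluate_concordance(
    calls: Iterable[Event] | set[Event], gold: GoldStandard
) -> ConcordanceResult:
    """Score a set of carrier events against the gold standard.

    With an empty gold standard the TPR is undefined; it is reported as
    ``None`` (never coerced to 0 or 1) and formats as "undefined".
    """
    called = set(calls)
    validated = set(gold.validated)
    tp_events = called & validated
    fp_events = called - validated
    fn_events = validated - called
    rows = (
        [{"sample_id": s, "event": e, "status": "TP"} for s, e in sorted(tp_events)]
        + [{"sample_id": s, "event": e, "status": "FP"} for s, e in sorted(fp_events)]
        + [{"sample_id": s, "event": e, "status": "FN"} for s, e in sorted(fn_events)]
    )
    breakdown = pd.DataFrame(rows, columns=["sample_id", "event", "status"])
    return ConcordanceResult(
        tp=len(tp_events), fp=len(fp_events), fn=len(fn_events), breakdown=breakdown
    )


def compare_methods(
    callsets: Mapping[str, Iterable[Event]], gold: GoldStandard
) -> pd.DataFrame:
    """One concordance row per platform, best TPR first.

    Sorted by TPR descending, ties broken by FDR ascending, then platform
    name, so equal platforms appear in a stable order.
    """
    if not callsets:
        raise ValueError("compare_methods needs at least one platform")
    rows = []
    for platform, events in callsets.items():
        res = evaluate_concordance(events, gold)
        rows.append(
            {
                "platform": platform,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "tpr": res.tpr,
                "fdr": res.fdr,
                "tpr_formatted": res.tpr_formatted,
                "fdr_formatted": res.fdr_formatted,
            }
        )
    table = pd.DataFrame(rows)
    table["_tpr"] = table["tpr"].fillna(-1.0)
    table["_fdr"] = table["fdr"].fillna(2.0)
    table = (
        table.sort_values(["_tpr", "_fdr", "platform"], ascending=[False, True, True])
        .drop(columns=["_tpr", "_fdr"])
        .reset_index(drop=True)
    )
    return table
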