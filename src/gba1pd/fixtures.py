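"""Deterministic fixtures reproducing the study's printed count tables.

These are hand-built, seedless tables — not samples from the simulator — so
every count matches the published figures exactly:

* ``fixture_72``: the 72-sample three-platform comparison (6 Sanger-validated
  carriers: p.E365K x3, p.T408M, p.N409S, one RecNciI);
* ``fixture_full``: the 1568-sample long-read vs array comparison (135
  validated carriers; the array calls 47, of which 36 validate);
* ``fixture_exclusion``: the 1568-participant cohort with the flag counts the
  exclusion cascade removes (14 other-gene/CNV carriers, 64 extra family
  members, 74 young related HC, 6 ancestry outliers -> 1410 remain);
* ``fixture_table1``: the post-exclusion analysis cohort (637 PD / 98
  atypical parkinsonism / 675 HC) with the carrier-class distribution behind
  the frequency and odds-ratio tables;
* ``load_vus_fixture``: the 12 variants of unknown significance with their
  carrier context and in-silico score calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from gba1pd.cohort import CORE_COLUMNS, validate_cohort
from gba1pd.concordance import CallRecord, Event, GoldStandard
from gba1pd.variants import GbaVariant

__all__ = [
    "ConcordanceFixture",
    "fixture_72",
    "fixture_full",
    "fixture_exclusion",
    "fixture_table1",
    "load_vus_fixture",
]


@dataclass
class ConcordanceFixture:
    """A gold standard plus per-platform carrier-event callsets."""

    n_samples: int
    gold: GoldStandard
    callsets: dict[str, set[Event]]
    records: dict[str, list[CallRecord]] = field(default_factory=dict)


def _var(hgvs_p: str, phase: str | None = None) -> GbaVariant:
    return GbaVariant(hgvs_p=hgvs_p, phase_group=phase, maf_nfe=0.001, qual=50.0)


def fixture_72() -> ConcordanceFixture:
    """The 72-sample comparison of long-read, WGS and array calls."""
    gold_events: list[Event] = [
        ("S01", "p.E365K"),
        ("S02", "p.E365K"),
        ("S03", "p.E365K"),
        ("S04", "p.T408M"),
        ("S05", "p.N409S"),
        ("S06", "RecNciI"),
    ]
    gold = GoldStandard.from_pairs(gold_events)
    single_events = set(gold_events[:5])
    callsets = {
        # long-read amplicon sequencing: all six carriers, no false calls
        "pacbio": set(gold_events),
        # WGS with the dedicated GBA recombinant caller: identical
        "wgs_gauchian": set(gold_events),
        # WGS with a generic short-read pipeline: misses the recombinant
        "wgs_gatk": set(single_events),
        # array genotyping: one validated call and two pseudogene artifacts
        "neurochip": {("S04", "p.T408M"), ("S70", "p.N431S"), ("S71", "p.A215D")},
    }
    # the long-read platform reports the recombinant as three phased components
    pacbio_records = [
        CallRecord("S01", _var("p.E365K"), "pacbio"),
        CallRecord("S02", _var("p.E365K"), "pacbio"),
        CallRecord("S03", _var("p.E365K"), "pacbio"),
        CallRecord("S04", _var("p.T408M"), "pacbio"),
        CallRecord("S05", _var("p.N409S"), "pacbio"),
        CallRecord("S06", _var("p.L483P", "S06:hap1"), "pacbio"),
        CallRecord("S06", _var("p.A495P", "S06:hap1"), "pacbio"),
        CallRecord("S06", _var("p.V499V", "S06:hap1"), "pacbio"),
    ]
    return ConcordanceFixture(
        n_samples=72, gold=gold, callsets=callsets, records={"pacbio": pacbio_records}
    )


def fixture_full() -> ConcordanceFixture:
    """The 1568-sample long-read vs array comparison (135 validated carriers)."""
    # carrier-class composition of the 135 validated carriers
    composition = (
        [("p.L483P", 25), ("p.N409S", 10), ("p.E365K", 72), ("p.K13R", 22), ("p.T369T", 6)]
    )
    gold_events: list[Event] = []
    i = 1
    for name, count in composition:
        for _ in range(count):
            gold_events.append((f"G{i:04d}", name))
            i += 1
    assert len(gold_events) == 135
    gold = GoldStandard.from_pairs(gold_events)
    # array: 36 validated calls plus 11 pseudogene-driven false positives
    neurochip = set(gold_events[:36]) | {
        (f"G{j:04d}", "p.N431S") for j in range(1500, 1511)
    }
    assert len(neurochip) == 47
    callsets = {"pacbio": set(gold_events), "neurochip": neurochip}
    return ConcordanceFixture(n_samples=1568, gold=gold, callsets=callsets)


def _base_row(pid: str, group: str, **kw) -> dict:
    row = {
        "id": pid,
        "family_id": kw.pop("family_id", pid),
        "group": group,
        "sex": kw.pop("sex", "M"),
        "aao": kw.pop("aao", np.nan),
        "aaa": kw.pop("aaa", 65.0),
        "disease_duration": kw.pop("disease_duration", np.nan),
        "pc1": kw.pop("pc1", 0.0),
        "pc2": kw.pop("pc2", 0.0),
        "first_degree_pd_relative": kw.pop("first_degree_pd_relative", 0),
        "other_gene_pathogenic": kw.pop("other_gene_pathogenic", 0),
        "cnv_carrier": kw.pop("cnv_carrier", 0),
        "family_history": kw.pop("family_history", 0),
        "carrier_class": kw.pop("carrier_class", "none"),
        "variants": kw.pop("variants", ""),
    }
    if kw:
        raise TypeError(f"unknown fields: {sorted(kw)}")
    return row


def _finish(rows: list[dict]) -> pd.DataFrame:
    cohort = pd.DataFrame(rows, columns=CORE_COLUMNS)
    # deterministic +-0.001 jitter keeps PC variance nonzero without outliers
    jitter = np.where(np.arange(len(cohort)) % 2 == 0, 0.001, -0.001)
    cohort["pc1"] = cohort["pc1"] + jitter
    cohort["pc2"] = cohort["pc2"] - jitter
    validate_cohort(cohort)
    return cohort


def fixture_exclusion() -> pd.DataFrame:
    """The full 1568-participant cohort the exclusion cascade starts from.

    Flags are non-overlapping so each cascade step removes exactly the
    printed count: 14 other-gene/CNV carriers, 64 extra family members
    (8 PD, 2 atypical, 54 HC), 74 young HC with a PD relative, and 6
    ancestry outliers (3 patients, 3 HC).
    """
    rows: list[dict] = []
    pd_i = park_i = hc_i = 0

    def next_pd() -> str:
        nonlocal pd_i
        pd_i += 1
        return f"P{pd_i:04d}"

    def next_hc() -> str:
        nonlocal hc_i
        hc_i += 1
        return f"H{hc_i:04d}"

    # --- PD patients (660) ---
    for _ in range(8):
        rows.append(_base_row(next_pd(), "PD", aao=60.0, aaa=65.0, disease_duration=5.0,
                              other_gene_pathogenic=1))
    for _ in range(4):
        rows.append(_base_row(next_pd(), "PD", aao=60.0, aaa=65.0, disease_duration=5.0,
                              cnv_carrier=1))
    for fam in range(8):  # 8 two-case families; earliest onset is the proband
        fid = f"FPD{fam:02d}"
        rows.append(_base_row(next_pd(), "PD", family_id=fid, aao=50.0, aaa=60.0,
                              disease_duration=10.0))
        rows.append(_base_row(next_pd(), "PD", family_id=fid, aao=60.0, aaa=65.0,
                              disease_duration=5.0))
    for _ in range(3):  # non-European ancestry
        rows.append(_base_row(next_pd(), "PD", aao=60.0, aaa=65.0, disease_duration=5.0,
                              pc1=1.0))
    while pd_i < 660:
        rows.append(_base_row(next_pd(), "PD", aao=60.0, aaa=65.0, disease_duration=5.0))

    # --- atypical parkinsonism (100: 60 PSP, 25 DLB, 14 MSA, 1 FTDP) ---
    for fam in range(2):  # 2 two-case PSP families
        fid = f"FPK{fam:02d}"
        for aao in (55.0, 65.0):
            park_i += 1
            rows.append(_base_row(f"K{park_i:04d}", "PSP", family_id=fid, aao=aao,
                                  aaa=aao + 5, disease_duration=5.0))
    for group, n in (("PSP", 56), ("DLB", 25), ("MSA", 14), ("FTDP", 1)):
        for _ in range(n):
            park_i += 1
            rows.append(_base_row(f"K{park_i:04d}", group, aao=65.0, aaa=70.0,
                                  disease_duration=5.0))

    # --- healthy controls (808) ---
    for _ in range(2):
        rows.append(_base_row(next_hc(), "HC", other_gene_pathogenic=1))
    for fam in range(54):  # 54 two-control families
        fid = f"FHC{fam:02d}"
        rows.append(_base_row(next_hc(), "HC", family_id=fid, aaa=62.0))
        rows.append(_base_row(next_hc(), "HC", family_id=fid, aaa=64.0))
    for _ in range(74):  # young HC with a first-degree PD relative
        rows.append(_base_row(next_hc(), "HC", aaa=55.0, first_degree_pd_relative=1))
    for _ in range(3):  # non-European ancestry
        rows.append(_base_row(next_hc(), "HC", pc1=1.0))
    while hc_i < 808:
        rows.append(_base_row(next_hc(), "HC", aaa=65.0))

    cohort = _finish(rows)
    assert len(cohort) == 1568
    return cohort


def fixture_table1() -> pd.DataFrame:
    """The post-exclusion analysis cohort with the published carrier counts.

    637 PD (21 severe, 7 mild, 39 risk, 10 VUS-only, 6 synonymous-only, 554
    non-carriers), 98 atypical parkinsonism (4 risk carriers), 675 HC
    (2 severe, 2 mild, 25 risk, 5 VUS-only).  Ages at onset encode the
    early-onset counts (5/2/1/40 with AAO 40) and family-history flags the
    25/67 vs 141/554 comparison.
    """
    rows: list[dict] = []
    i = 0

    def add(group: str, n: int, *, carrier_class: str = "none", variants: str = "",
            n_early: int = 0, n_famhist: int = 0, aaa: float = 67.0) -> None:
        nonlocal i
        for k in range(n):
            i += 1
            early = k < n_early
            aao = 40.0 if early else 60.0
            patient = group != "HC"
            rows.append(
                _base_row(
                    f"T{i:04d}",
                    group,
                    aao=aao if patient else np.nan,
                    aaa=aaa if patient else 61.0,
                    disease_duration=(aaa - aao) if patient else np.nan,
                    carrier_class=carrier_class,
                    variants=variants,
                    family_history=1 if k < n_famhist else 0,
                )
            )

    add("PD", 21, carrier_class="severe", variants="p.L483P", n_early=5, n_famhist=8)
    add("PD", 7, carrier_class="mild", variants="p.N409S", n_early=2, n_famhist=2)
    add("PD", 39, carrier_class="risk", variants="p.E365K", n_early=1, n_famhist=15)
    add("PD", 10, carrier_class="vus", variants="p.K13R")
    add("PD", 6, carrier_class="synonymous", variants="p.T369T")
    add("PD", 554, n_early=40, n_famhist=141)

    add("PSP", 2, carrier_class="risk", variants="p.E365K")
    add("PSP", 57)
    add("DLB", 2, carrier_class="risk", variants="p.T408M")
    add("DLB", 22)
    add("MSA", 14)
    add("FTDP", 1)

    add("HC", 2, carrier_class="severe", variants="p.L483P")
    add("HC", 2, carrier_class="mild", variants="p.N409S")
    add("HC", 25, carrier_class="risk", variants="p.E365K")
    add("HC", 5, carrier_class="vus", variants="p.K13R")
    add("HC", 641)

    cohort = _finish(rows)
    assert len(cohort) == 1410
    return cohort


def load_vus_fixture() -> pd.DataFrame:
    """The 12 VUS with carrier context and in-silico score calls."""
    with resources.files("gba1pd").joinpath("data/vus_annotations.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t")
    for col in ("revel_call", "cadd_call", "hgmd_label", "clinvar_label",
                "secondary_structure"):
        table[col] = table[col].astype(object).where(table[col].notna(), None)
    return table
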