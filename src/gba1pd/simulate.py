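"""Seeded synthetic case-control cohorts with GBA1 carrier structure.

The generator emulates the statistical shape the analysis layer assumes: a
PD-dominated patient arm and healthy controls, carrier classes assigned at
configurable frequencies (defaults follow the observed post-exclusion
frequencies: ~10.5% pathogenic carriers in PD, ~4.3% in HC), family
clusters inside one diagnostic arm, ancestry PCs with occasional outliers,
exclusion flags, and clinical outcomes generated from a linear (continuous
scales) or logistic (binary symptoms) model with configurable carrier-class
effects and sex/age/duration covariates.

Randomness is split into named substreams (structure, genotype, clinical,
missingness) derived from one mandatory seed, so e.g. changing the clinical
noise stream never changes who carries what.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from gba1pd.cohort import CORE_COLUMNS, validate_cohort

__all__ = [
    "SimulationConfig",
    "OutcomeSpec",
    "PlatformProfile",
    "simulate_cohort",
    "simulate_platform_callset",
]


@dataclass
class OutcomeSpec:
    """One clinical outcome: linear with Gaussian noise, or logistic."""

    family: str  # "linear" | "logistic"
    intercept: float  # mean scale value (linear) or baseline logit (logistic)
    noise_sd: float = 0.0  # linear only
    effects: Mapping[str, float] = field(default_factory=dict)  # carrier class -> beta
    covariates: Mapping[str, float] = field(default_factory=dict)


def _default_outcomes() -> dict[str, OutcomeSpec]:
    cov = {"sex": 0.3, "aaa": 0.05, "disease_duration": 0.3}
    return {
        "updrs1": OutcomeSpec("linear", 10.5, 7.0, {"severe": 4.0}, cov),
        "updrs2": OutcomeSpec("linear", 11.4, 8.3, {"severe": 1.2}, cov),
        "updrs3": OutcomeSpec("linear", 34.6, 16.2, {}, cov),
        "bdi": OutcomeSpec("linear", 9.9, 7.1, {"severe": 4.0}, cov),
        "moca": OutcomeSpec("linear", 24.4, 4.5, {"severe": -0.8}, {"aaa": -0.05}),
        "pdq39": OutcomeSpec("linear", 39.3, 26.7, {"severe": 9.5}, cov),
        "ledd": OutcomeSpec("linear", 513.0, 405.0, {"severe": 118.0}, {"disease_duration": 20.0}),
        "hallucinations": OutcomeSpec("logistic", -1.73, 0.0, {"severe": 1.2}),
        "gait_disorder": OutcomeSpec("logistic", 0.2, 0.0, {"severe": 0.9}),
    }


def _default_class_freq() -> dict[str, dict[str, float]]:
    # post-exclusion carrier frequencies: PD 67/637 pathogenic, HC 29/675
    return {
        "PD": {"severe": 21 / 637, "mild": 7 / 637, "risk": 39 / 637,
               "vus": 10 / 637, "synonymous": 6 / 637},
        "PSP": {"risk": 2 / 59},
        "DLB": {"risk": 2 / 24},
        "HC": {"severe": 2 / 675, "mild": 2 / 675, "risk": 25 / 675,
               "vus": 5 / 675},
    }


def _default_variant_pool() -> dict[str, list[tuple[str, float]]]:
    return {
        "severe": [("p.L483P", 0.6), ("RecNciI", 0.25), ("p.R398*", 0.15)],
        "mild": [("p.N409S", 1.0)],
        "risk": [("p.E365K", 0.6), ("p.T408M", 0.4)],
        "vus": [("p.K13R", 0.5), ("p.E427K", 0.5)],
        "synonymous": [("p.T369T", 1.0)],
    }


@dataclass
class SimulationConfig:
    """Everything the cohort generator needs; the seed is mandatory."""

    seed: int
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"PD": 660, "PSP": 60, "DLB": 25, "MSA": 14,
                                 "FTDP": 1, "HC": 808}
    )
    class_freq: Mapping[str, Mapping[str, float]] = field(default_factory=_default_class_freq)
    variant_pool: Mapping[str, Sequence[tuple[str, float]]] = field(
        default_factory=_default_variant_pool
    )
    family_fraction: float = 0.08  # fraction of participants placed in 2-person families
    families_span_arms: bool = False
    aao_mean: float = 63.0
    aao_sd: float = 11.5
    aao_bounds: tuple[float, float] = (18.0, 90.0)
    hc_aaa_mean: float = 61.0
    hc_aaa_sd: float = 11.5
    hc_aaa_bounds: tuple[float, float] = (30.0, 95.0)
    duration_mean: float = 5.0
    duration_sd: float = 5.0
    duration_bounds: tuple[float, float] = (0.0, 30.0)
    male_fraction_patients: float = 0.664
    male_fraction_hc: float = 0.527
    other_gene_rate: float = 0.006
    cnv_rate_patients: float = 0.005
    young_related_hc_rate: float = 0.09
    pc_sd: float = 0.01
    pc_outlier_rate: float = 0.004
    pc_outlier_shift: float = 1.0
    outcomes: Mapping[str, OutcomeSpec] = field(default_factory=_default_outcomes)
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {"updrs1": 0.026, "updrs2": 0.023, "updrs3": 0.024,
                                 "bdi": 0.049, "moca": 0.021, "pdq39": 0.085,
                                 "ledd": 0.033}
    )
    clinical_seed: Optional[int] = None  # override for the clinical noise stream

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for group, freqs in self.class_freq.items():
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ValueError(f"carrier frequencies outside [0,1] for {group}")
            if sum(freqs.values()) > 1.0:
                raise ValueError(f"carrier class frequencies for {group} sum above 1")
        for klass, pool in self.variant_pool.items():
            total = sum(p for _, p in pool)
            if pool and not np.isclose(total, 1.0):
                raise ValueError(f"variant pool for {klass} does not sum to 1")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("structure", "genotype", "clinical", "missing")
    rngs = {n: np.random.default_rng(c) for n, c in zip(names, children)}
    if config.clinical_seed is not None:
        rngs["clinical"] = np.random.default_rng(
            np.random.SeedSequence(config.clinical_seed)
        )
    return rngs


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort table and its truth callset, deterministically.

    Returns ``(cohort, truth)`` where truth has one row per carrier event
    (sample_id, event, carrier_class, phase_group).
    """
    rngs = _streams(config)
    rng_s, rng_g, rng_c, rng_m = (rngs[k] for k in ("structure", "genotype",
                                                    "clinical", "missing"))
    rows: list[dict] = []
    idx = 0
    for group, n in config.n_per_group.items():
        patient = group != "HC"
        male_frac = config.male_fraction_patients if patient else config.male_fraction_hc
        if patient:
            aao = _truncnorm(rng_s, config.aao_mean, config.aao_sd, *config.aao_bounds, size=n)
            duration = _truncnorm(rng_s, config.duration_mean, config.duration_sd,
                                  *config.duration_bounds, size=n)
            aaa = aao + duration
        else:
            aao = np.full(n, np.nan)
            duration = np.full(n, np.nan)
            aaa = _truncnorm(rng_s, config.hc_aaa_mean, config.hc_aaa_sd,
                             *config.hc_aaa_bounds, size=n)
        sex = np.where(rng_s.random(n) < male_frac, "M", "F")
        pc = rng_s.normal(0.0, config.pc_sd, size=(n, 2))
        outlier = rng_s.random(n) < config.pc_outlier_rate
        pc[outlier, 0] += config.pc_outlier_shift
        other_gene = rng_s.random(n) < config.other_gene_rate
        cnv = patient & (rng_s.random(n) < config.cnv_rate_patients)
        related = (not patient) & (rng_s.random(n) < config.young_related_hc_rate)
        for i in range(n):
            idx += 1
            rows.append({
                "id": f"SIM{idx:05d}",
                "family_id": f"SIM{idx:05d}",
                "group": group,
                "sex": sex[i],
                "aao": round(aao[i], 1) if patient else np.nan,
                "aaa": round(float(aaa[i]), 1),
                "disease_duration": round(float(duration[i]), 1) if patient else np.nan,
                "pc1": pc[i, 0],
                "pc2": pc[i, 1],
                "first_degree_pd_relative": int(related[i]) if not patient else 0,
                "other_gene_pathogenic": int(other_gene[i]),
                "cnv_carrier": int(cnv[i]),
                "family_history": 0,
                "carrier_class": "none",
                "variants": "",
            })
    cohort = pd.DataFrame(rows, columns=CORE_COLUMNS)

    # family clusters of two inside one diagnostic arm (never across arms
    # unless configured)
    fam = 0
    arms = [cohort["group"] != "HC", cohort["group"] == "HC"]
    if config.families_span_arms:
        arms = [pd.Series(True, index=cohort.index)]
    for arm_mask in arms:
        members = cohort.index[arm_mask]
        n_pairs = int(len(members) * config.family_fraction / 2)
        chosen = rng_s.choice(members, size=2 * n_pairs, replace=False)
        for k in range(n_pairs):
            fam += 1
            cohort.loc[chosen[2 * k: 2 * k + 2], "family_id"] = f"FAM{fam:04d}"

    # carrier classes and variants
    truth_rows: list[dict] = []
    u = rng_g.random(len(cohort))
    for pos, (i, row) in enumerate(cohort.iterrows()):
        freqs = config.class_freq.get(row["group"], {})
        cum = 0.0
        chosen_class = "none"
        for klass, f in freqs.items():
            cum += f
            if u[pos] < cum:
                chosen_class = klass
                break
        if chosen_class == "none":
            continue
        pool = list(config.variant_pool[chosen_class])
        names = [nm for nm, _ in pool]
        probs = np.array([p for _, p in pool])
        event = names[rng_g.choice(len(names), p=probs)]
        cohort.at[i, "carrier_class"] = chosen_class
        cohort.at[i, "variants"] = event
        truth_rows.append({
            "sample_id": row["id"],
            "event": event,
            "carrier_class": chosen_class,
            "phase_group": f"{row['id']}:hap1" if event == "RecNciI" else "",
        })
    truth = pd.DataFrame(truth_rows,
                         columns=["sample_id", "event", "carrier_class", "phase_group"])

    # clinical outcomes
    patient_mask = (cohort["group"] != "HC").to_numpy()
    sex_num = (cohort["sex"] == "M").to_numpy(dtype=float)
    aaa_c = cohort["aaa"].to_numpy(dtype=float) - 65.0
    dur = np.nan_to_num(cohort["disease_duration"].to_numpy(dtype=float))
    for name, spec in config.outcomes.items():
        beta = cohort["carrier_class"].map(lambda c: spec.effects.get(c, 0.0)).to_numpy()
        lin = (
            spec.intercept
            + beta
            + spec.covariates.get("sex", 0.0) * sex_num
            + spec.covariates.get("aaa", 0.0) * aaa_c
            + spec.covariates.get("disease_duration", 0.0) * dur
        )
        if spec.family == "linear":
            values = lin + rng_c.normal(0.0, spec.noise_sd, size=len(cohort))
        else:
            p = 1.0 / (1.0 + np.exp(-lin))
            values = (rng_c.random(len(cohort)) < p).astype(float)
        values = np.where(patient_mask, values, np.nan)  # scales assessed in patients
        rate = config.missingness.get(name, 0.0)
        if rate > 0:
            values = np.where(rng_m.random(len(cohort)) < rate, np.nan, values)
        cohort[name] = values

    validate_cohort(cohort)
    return cohort, truth


@dataclass
class PlatformProfile:
    """Error model of one calling platform."""

    name: str
    fn_rate: float = 0.0  # probability a true carrier event is missed
    fp_rate: float = 0.0  # expected false calls per sample
    fp_variant_pool: Sequence[str] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.fn_rate <= 1 or not 0 <= self.fp_rate <= 1:
            raise ValueError("platform error rates must lie in [0,1]")
        if self.fp_rate > 0 and not self.fp_variant_pool:
            raise ValueError("fp_rate > 0 requires a non-empty fp_variant_pool")


def simulate_platform_callset(
    truth: pd.DataFrame,
    profile: PlatformProfile,
    seed: int,
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Corrupt the truth callset with platform-specific FN/FP errors.

    Each true event is dropped independently with ``fn_rate``; false events
    are injected per sample with probability ``fp_rate`` (variant drawn
    uniformly from the profile's pool).  ``sample_ids`` defaults to the
    samples present in the truth set; pass the full cohort's ids so
    non-carriers can receive false calls too.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    keep = rng.random(len(truth)) >= profile.fn_rate
    called = truth.loc[keep, ["sample_id", "event"]].copy()
    if sample_ids is None:
        sample_ids = sorted(truth["sample_id"].unique())
    fp_rows = []
    if profile.fp_rate > 0:
        hit = rng.random(len(sample_ids)) < profile.fp_rate
        for sid, h in zip(sample_ids, hit):
            if h:
                event = profile.fp_variant_pool[rng.integers(len(profile.fp_variant_pool))]
                fp_rows.append({"sample_id": sid, "event": event})
    callset = pd.concat([called, pd.DataFrame(fp_rows, columns=["sample_id", "event"])],
                        ignore_index=True)
    callset = callset.drop_duplicates().reset_index(drop=True)
    callset["platform"] = profile.name
    return callset
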