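"""Carrier frequencies, odds ratios, adjusted regressions, BH correction.

Unadjusted odds ratios use the cross-product estimate OR = ad/bc with the
Woolf confidence interval exp(ln OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)),
adding the Haldane-Anscombe 0.5 to every cell when any cell is zero.  Both a
Fisher exact and a Wald p value are reported.  Genotype-phenotype models are
linear (continuous scales) or logistic (binary symptoms) regressions of the
outcome on carrier status, adjusted for sex, age at assessment and disease
duration, with listwise deletion per outcome.  Multiplicity is handled by
Benjamini-Hochberg within each comparison suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from gba1pd.cohort import ANY_CARRIER_CLASSES, CORE_COLUMNS, PATHOGENIC_CLASSES
from gba1pd.formatting import round_or, trunc_or, trunc_pct

__all__ = [
    "ContingencyTable",
    "EffectEstimate",
    "FrequencyResult",
    "RegressionSpec",
    "DegenerateModelError",
    "carrier_frequency",
    "odds_ratio",
    "fit_adjusted_model",
    "adjust_bh",
    "run_comparison_suites",
]

DEFAULT_COVARIATES = ("sex", "aaa", "disease_duration")
EARLY_ONSET_AAO = 45.0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure table: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if min(self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d) == 0:
            raise ValueError("zero margin: odds ratio undefined")


@dataclass
class EffectEstimate:
    kind: str  # "odds_ratio" or "beta"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("point estimate outside its confidence interval")

    @property
    def formatted(self) -> str:
        if self.kind == "odds_ratio":
            return trunc_or(self.estimate)
        return round_or(self.estimate)

    @property
    def formatted_rounded(self) -> str:
        return round_or(self.estimate)


@dataclass
class FrequencyResult:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def formatted(self) -> str:
        # frequency tables round to one decimal (12.088% prints as 12.1%),
        # unlike the truncated concordance rates and odds ratios
        return f"{self.fraction * 100:.1f}%"


def carrier_frequency(
    cohort: pd.DataFrame,
    group: pd.Series | str,
    classes: Sequence[str] = ANY_CARRIER_CLASSES,
) -> FrequencyResult:
    """Carrier frequency within one diagnostic group.

    ``group`` is a group label ("PD", "HC", ...) or a boolean mask;
    ``classes`` the carrier classes counted as exposed.
    """
    mask = (cohort["group"] == group) if isinstance(group, str) else group
    denom = int(mask.sum())
    if denom == 0:
        raise ValueError("empty group for carrier frequency")
    num = int((mask & cohort["carrier_class"].isin(classes)).sum())
    return FrequencyResult(numerator=num, denominator=denom)


def odds_ratio(table: ContingencyTable, ci_level: float = 0.95) -> EffectEstimate:
    """Cross-product odds ratio with a Woolf confidence interval."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:  # Haldane-Anscombe continuity correction
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    estimate = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zcrit = sps.norm.ppf(0.5 + ci_level / 2)
    log_or = np.log(estimate)
    ci_low, ci_high = np.exp(log_or - zcrit * se), np.exp(log_or + zcrit * se)
    p_wald = 2 * sps.norm.sf(abs(log_or) / se)
    _, p_fisher = sps.fisher_exact([[table.a, table.b], [table.c, table.d]])
    return EffectEstimate(
        kind="odds_ratio",
        estimate=float(estimate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p_fisher),
        extras={"p_wald": float(p_wald), "p_fisher": float(p_fisher), "table": table},
    )


@dataclass
class RegressionSpec:
    outcome: str
    family: str  # "linear" or "logistic"
    predictor: str = "carrier"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")


class DegenerateModelError(RuntimeError):
    """Constant outcome, empty arm, or (quasi-)separated logistic fit."""


def fit_adjusted_model(cohort: pd.DataFrame, spec: RegressionSpec) -> EffectEstimate:
    """Fit the adjusted genotype-phenotype model and report the carrier beta.

    Rows with a missing outcome, predictor or covariate are dropped
    (listwise deletion).  The returned estimate is the carrier coefficient
    with its 95% Wald interval; ``extras`` records the sample size and the
    number of rows deleted.
    """
    cols = [spec.outcome, spec.predictor, *spec.covariates]
    data = cohort[cols].copy()
    if "sex" in data.columns and data["sex"].dtype == object:
        data["sex"] = (data["sex"] == "M").astype(float)
    data = data.apply(pd.to_numeric)
    n_total = len(data)
    data = data.dropna()
    if len(data) < len(cols) + 2:
        raise DegenerateModelError(f"{spec.outcome}: too few complete rows ({len(data)})")
    y = data[spec.outcome].to_numpy(dtype=float)
    X = sm.add_constant(data[[spec.predictor, *spec.covariates]].astype(float))
    if np.unique(y).size < 2:
        raise DegenerateModelError(f"{spec.outcome}: constant outcome")
    if data[spec.predictor].nunique() < 2:
        raise DegenerateModelError(f"{spec.outcome}: constant predictor")
    if spec.family == "linear":
        fit = sm.OLS(y, X).fit()
    else:
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"{spec.outcome}: logistic outcome must be 0/1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
    beta = float(fit.params[spec.predictor])
    se = float(fit.bse[spec.predictor])
    if not np.isfinite(se) or se > 1e3:
        raise DegenerateModelError(f"{spec.outcome}: unstable fit (separation?)")
    ci = fit.conf_int().loc[spec.predictor]
    return EffectEstimate(
        kind="beta",
        estimate=beta,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[spec.predictor]),
        extras={"n": int(len(data)), "n_missing": int(n_total - len(data)),
                "family": spec.family},
    )


def adjust_bh(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, aligned to the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def infer_outcomes(cohort: pd.DataFrame) -> list[tuple[str, str]]:
    """Detect clinical outcome columns: 0/1 -> logistic, otherwise linear."""
    outcomes = []
    for col in cohort.columns:
        if col in CORE_COLUMNS:
            continue
        series = pd.to_numeric(cohort[col], errors="coerce")
        if series.notna().sum() == 0:
            continue
        values = set(series.dropna().unique())
        family = "logistic" if values <= {0.0, 1.0} else "linear"
        outcomes.append((col, family))
    return outcomes


SUITES = {
    "pathogenic_vs_noncarrier": (tuple(PATHOGENIC_CLASSES), ("none",)),
    "severe_vs_noncarrier": (("severe",), ("none",)),
    "mild_vs_noncarrier": (("mild",), ("none",)),
    "risk_vs_noncarrier": (("risk",), ("none",)),
    "severe_vs_mild_risk": (("severe",), ("mild", "risk")),
}


def run_comparison_suites(
    cohort: pd.DataFrame,
    outcomes: Optional[Sequence[tuple[str, str]]] = None,
    group: str = "PD",
) -> dict[str, pd.DataFrame]:
    """Run the three genotype-phenotype comparison families on PD patients.

    Suite 1 compares pathogenic carriers (severe+mild+risk) with
    non-carriers, suite 2 each class with non-carriers, suite 3 severe with
    mild+risk carriers.  VUS-only and synonymous-only carriers are excluded
    from every arm.  BH adjustment is applied within each suite.
    """
    outcomes = list(outcomes) if outcomes is not None else infer_outcomes(cohort)
    patients = cohort[cohort["group"] == group]
    results: dict[str, pd.DataFrame] = {}
    for suite, (exposed, reference) in SUITES.items():
        arm = patients[patients["carrier_class"].isin(exposed + reference)].copy()
        arm["carrier"] = arm["carrier_class"].isin(exposed).astype(int)
        if arm["carrier"].sum() == 0 or (arm["carrier"] == 0).sum() == 0:
            warnings.warn(f"suite {suite}: empty arm, skipped", stacklevel=2)
            continue
        rows = []
        for outcome, family in outcomes:
            try:
                est = fit_adjusted_model(arm, RegressionSpec(outcome=outcome, family=family))
            except DegenerateModelError as exc:
                rows.append({"outcome": outcome, "family": family, "beta": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "n": np.nan, "note": str(exc)})
                continue
            rows.append({"outcome": outcome, "family": family, "beta": est.estimate,
                         "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                         "n": est.extras["n"], "note": ""})
        table = pd.DataFrame(rows)
        ok = table["p"].notna()
        table["p_adj"] = np.nan
        if ok.any():
            table.loc[ok, "p_adj"] = adjust_bh(table.loc[ok, "p"])
        table.attrs["n_exposed"] = int(arm["carrier"].sum())
        table.attrs["n_reference"] = int((arm["carrier"] == 0).sum())
        results[suite] = table
    return results


def early_onset_table(
    cohort: pd.DataFrame,
    carrier_classes: Sequence[str],
    threshold: float = EARLY_ONSET_AAO,
    strict: bool = False,
    group: str = "PD",
) -> ContingencyTable:
    """Early-onset (AAO <= threshold, or < when strict) carriers vs non-carriers."""
    patients = cohort[cohort["group"] == group]
    carrier = patients["carrier_class"].isin(carrier_classes)
    noncarrier = patients["carrier_class"] == "none"
    early = patients["aao"] < threshold if strict else patients["aao"] <= threshold
    return ContingencyTable(
        a=int((carrier & early).sum()),
        b=int((carrier & ~early).sum()),
        c=int((noncarrier & early).sum()),
        d=int((noncarrier & ~early).sum()),
    )
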