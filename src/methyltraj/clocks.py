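"""Epigenetic age prediction from beta values.

An epigenetic clock is a sparse linear predictor over CpG beta values,
optionally followed by a nonlinear output transform (the pan-tissue clock's
piecewise log/linear age transform) and a unit conversion.  Stage-wise age
differences are compared with a one-way ANOVA followed by Tukey's HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

DAYS_PER_YEAR = 365.25
GESTATION_DAYS = 280.0

VALID_TRANSFORMS = {"identity", "horvath_antitrafo"}
VALID_UNITS = {"years", "days_post_conception"}


class ClockError(ValueError):
    pass


@dataclass
class ClockModel:
    """Sparse linear clock: ``age = transform(intercept + sum coef_i * beta_i)``."""

    name: str
    coefficients: Dict[str, float]
    intercept: float
    transform: str = "identity"
    output_unit: str = "years"
    adult_age: float = 20.0

    def __post_init__(self):
        if not self.coefficients:
            raise ClockError("clock must have at least one coefficient")
        if self.transform not in VALID_TRANSFORMS:
            raise ClockError(f"unknown transform {self.transform!r}")
        if self.output_unit not in VALID_UNITS:
            raise ClockError(f"unknown output unit {self.output_unit!r}")

    @property
    def n_cpgs(self) -> int:
        return len(self.coefficients)


@dataclass
class AgePrediction:
    sample_id: str
    linear_predictor: float
    age: float
    n_missing_clock_cpgs: int


def horvath_antitrafo(m: float, adult_age: float = 20.0) -> float:
    """Inverse of the pan-tissue clock's age transform, in years.

    Exponential below the knot (child ages compressed on the model scale),
    linear above: ``(1+A) e^m - 1`` for ``m < 0``, ``(1+A) m + A`` otherwise.
    Continuous and strictly increasing; tends to -1 year as ``m -> -inf``.
    """
    m = float(m)
    if m < 0:
        return (1.0 + adult_age) * np.exp(m) - 1.0
    return (1.0 + adult_age) * m + adult_age


def years_to_days_post_conception(years: float) -> float:
    """Age in days post-conception, assuming full-term gestation of 280 days."""
    return years * DAYS_PER_YEAR + GESTATION_DAYS


def apply_clock(beta: pd.DataFrame, clock: ClockModel, strict: bool = False,
                convert_to: str | None = None) -> List[AgePrediction]:
    """Apply a clock to a probes x samples beta matrix.

    Clock CpGs absent from the matrix are skipped and counted (``strict=True``
    errors instead).  ``convert_to='days_post_conception'`` converts a
    years-scale clock onto the fetal-age scale for cross-clock comparison.
    """
    present = [p for p in clock.coefficients if p in beta.index]
    n_missing = clock.n_cpgs - len(present)
    if not present:
        raise ClockError(f"no CpGs of clock {clock.name!r} found in the beta matrix")
    if strict and n_missing:
        raise ClockError(f"clock {clock.name!r}: {n_missing} CpGs missing and strict=True")

    coefs = np.array([clock.coefficients[p] for p in present])
    sub = beta.loc[present].to_numpy()
    lin = clock.intercept + coefs @ sub

    preds = []
    for sid, m in zip(beta.columns, lin):
        if clock.transform == "horvath_antitrafo":
            age = horvath_antitrafo(m, clock.adult_age)
        else:
            age = float(m)
        if convert_to == "days_post_conception" and clock.output_unit == "years":
            age = years_to_days_post_conception(age)
        elif convert_to is not None and convert_to != clock.output_unit:
            raise ClockError(f"cannot convert {clock.output_unit} to {convert_to}")
        preds.append(AgePrediction(sample_id=sid, linear_predictor=float(m),
                                   age=age, n_missing_clock_cpgs=n_missing))
    return preds


def predictions_to_frame(preds: List[AgePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in preds],
            "linear_predictor": [p.linear_predictor for p in preds],
            "age": [p.age for p in preds],
            "n_missing_clock_cpgs": [p.n_missing_clock_cpgs for p in preds],
        }
    ).set_index("sample_id")


@dataclass
class StageComparison:
    anova_F: float
    anova_p: float
    pairwise: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage_a": a, "stage_b": b, "mean_diff": d, "p_adj": p}
            for (a, b), (d, p) in self.pairwise.items()
        ]
        return pd.DataFrame(rows)


def stage_anova_tukey(ages, stages) -> StageComparison:
    """One-way ANOVA across stages followed by Tukey's HSD on all pairs.

    Uses Tukey–Kramer standard errors, so unbalanced groups (e.g. after QC
    removed samples from one stage) are handled.  With zero residual variance
    the p-values are reported as 0 with a warning.
    """
    ages = np.asarray(ages, dtype=float)
    stages = np.asarray(stages)
    levels = list(pd.unique(stages))
    if len(levels) < 2:
        raise ClockError("need at least 2 stages")
    groups = [ages[stages == lv] for lv in levels]
    if any(len(g) < 1 for g in groups):
        raise ClockError("every stage needs at least one sample")
    n_total = len(ages)
    if n_total - len(levels) < 2:
        raise ClockError("need at least 2 residual degrees of freedom")

    resid_var = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n_total - len(levels))
    if resid_var == 0:
        warnings.warn("zero residual variance; p-values reported as 0")
        comp = StageComparison(anova_F=np.inf, anova_p=0.0)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                diff = groups[j].mean() - groups[i].mean()
                comp.pairwise[(levels[i], levels[j])] = (float(diff), 0.0)
        return comp

    F, p = stats.f_oneway(*groups)
    res = pairwise_tukeyhsd(ages, stages)
    comp = StageComparison(anova_F=float(F), anova_p=float(p))
    # statsmodels orders pairs over sorted unique groups
    uniq = list(res.groupsunique)
    k = 0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            comp.pairwise[(str(uniq[i]), str(uniq[j]))] = (
                float(res.meandiffs[k]),
                float(res.pvalues[k]),
            )
            k += 1
    return comp


def read_clock_csv(path) -> ClockModel:
    """Read a clock coefficient CSV.

    Format: optional ``# key: value`` metadata header lines (name, transform,
    output_unit, adult_age), then ``probe_id,coefficient`` rows with a
    reserved ``(Intercept)`` row.
    """
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            name, _, val = line.partition(",")
            if name == "probe_id":
                continue
            rows.append((name, float(val)))
    intercept = 0.0
    coefs = {}
    for name, val in rows:
        if name == "(Intercept)":
            intercept = val
        else:
            coefs[name] = val
    return ClockModel(
        name=meta.get("name", "clock"),
        coefficients=coefs,
        intercept=intercept,
        transform=meta.get("transform", "identity"),
        output_unit=meta.get("output_unit", "years"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


def write_clock_csv(clock: ClockModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {clock.name}\n")
        fh.write(f"# transform: {clock.transform}\n")
        fh.write(f"# output_unit: {clock.output_unit}\n")
        fh.write(f"# adult_age: {clock.adult_age}\n")
        fh.write("probe_id,coefficient\n")
        fh.write(f"(Intercept),{clock.intercept!r}\n")
        for pid, c in clock.coefficients.items():
            fh.write(f"{pid},{c!r}\n")
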