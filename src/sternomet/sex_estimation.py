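"""Sex estimation from sternal measurements via linear discriminant functions.

Ships the nine published discriminant functions (three-variable, five
single-measurement, three index functions) with their sectioning points, and
can refit two-group Fisher discriminants on labeled measurement tables with
resubstitution or leave-one-out validation.

A discriminant score is ``sum(coefficient * value) + constant``; scores above
the sectioning point classify as male, below as female, exactly at the point
as indeterminate (configurable).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DiscriminantFunction",
    "ClassificationReport",
    "builtin_functions",
    "score_function",
    "classify_sex",
    "fit_discriminant",
    "loocv_classification",
    "sex_difference_test",
    "two_sample_t",
]

VARIABLES = ("M", "MW", "B", "CSW1", "CSW2", "CL", "SI", "SA")


@dataclass(frozen=True)
class DiscriminantFunction:
    """A linear discriminant with a sectioning point (score > point -> male)."""

    name: str
    variables: tuple
    coefficients: tuple
    constant: float
    sectioning_point: float

    def __post_init__(self):
        if len(self.variables) != len(self.coefficients):
            raise ValueError("one coefficient per variable required")


@dataclass(frozen=True)
class ClassificationReport:
    """Per-sex and overall correct-classification rates (percent)."""

    rate_male: float
    rate_female: float
    rate_overall: float
    n_male: int
    n_female: int
    mode: str  # "resubstitution" | "leave-one-out"

    def __post_init__(self):
        for r in (self.rate_male, self.rate_female, self.rate_overall):
            if not 0.0 <= r <= 100.0:
                raise ValueError("rates must lie in [0, 100]")
        n = self.n_male + self.n_female
        if n:
            weighted = (self.n_male * self.rate_male
                        + self.n_female * self.rate_female) / n
            if abs(weighted - self.rate_overall) > 1e-6:
                raise ValueError("overall rate must be the sample-size "
                                 "weighted mean of the per-sex rates")


def builtin_functions() -> list[DiscriminantFunction]:
    """The nine published discriminant functions, verbatim."""
    text = resources.files("sternomet.data").joinpath(
        "discriminant_functions.json").read_text()
    payload = json.loads(text)
    return [
        DiscriminantFunction(
            name=f["name"],
            variables=tuple(f["variables"]),
            coefficients=tuple(f["coefficients"]),
            constant=float(f["constant"]),
            sectioning_point=float(f["sectioning_point"]),
        )
        for f in payload["functions"]
    ]


def _record_value(record, name: str):
    if isinstance(record, Mapping):
        v = record.get(name)
    else:
        v = getattr(record, name, None)
    if (v is None or (isinstance(v, float) and np.isnan(v))) \
            and not isinstance(record, Mapping):
        v = None
    return v


def score_function(f: DiscriminantFunction, record) -> float:
    """Evaluate the discriminant score on a record (mapping or object).

    Index variables (SI, SA, CL) must already be present on the record;
    see :func:`sternomet.osteometry.compute_indices`.
    """
    total = f.constant
    for name, coef in zip(f.variables, f.coefficients):
        v = _record_value(record, name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"record is missing variable {name!r} "
                             f"required by function {f.name!r}")
        total += coef * float(v)
    return float(total)


def classify_sex(f: DiscriminantFunction, record, *,
                 tie_policy: str = "indeterminate") -> str:
    """male iff score > sectioning point, female iff below; ties per policy."""
    if tie_policy not in ("indeterminate", "male", "female"):
        raise ValueError(f"invalid tie policy {tie_policy!r}")
    s = score_function(f, record)
    if s > f.sectioning_point:
        return "male"
    if s < f.sectioning_point:
        return "female"
    return tie_policy


def _design(records: pd.DataFrame, variables: Sequence[str]):
    X = records.loc[:, list(variables)].to_numpy(dtype=float)
    sex = records["sex"].str.lower().to_numpy()
    if not np.isin(sex, ("male", "female")).all():
        raise ValueError("sex column must contain only male/female")
    return X, sex


def fit_discriminant(records: pd.DataFrame,
                     variables: Sequence[str],
                     name: str = "custom",
                     prior_weighted_point: bool = False) -> DiscriminantFunction:
    """Two-group Fisher discriminant on a labeled measurement table.

    The coefficient vector is proportional to pooled-within-covariance^-1
    times the mean difference, scaled so the pooled within-group score
    variance is 1; the constant centers the grand-mean score at 0, and the
    sectioning point is the midpoint of the two group mean scores
    (equal priors; sample-size weighted if ``prior_weighted_point``).  The
    orientation is normalized so the male mean score exceeds the female one.
    """
    X, sex = _design(records, variables)
    Xm, Xf = X[sex == "male"], X[sex == "female"]
    nm, nf = len(Xm), len(Xf)
    if nm < 2 or nf < 2:
        raise ValueError(f"need >= 2 records per sex (got {nm} male, {nf} female)")
    mum, muf = Xm.mean(axis=0), Xf.mean(axis=0)
    Sw = ((nm - 1) * np.cov(Xm.T).reshape(len(variables), -1)
          + (nf - 1) * np.cov(Xf.T).reshape(len(variables), -1)) / (nm + nf - 2)
    try:
        w = np.linalg.solve(Sw, mum - muf)
    except np.linalg.LinAlgError as e:
        raise ValueError("pooled within-group covariance is singular") from e
    scale2 = float(w @ Sw @ w)
    if scale2 < 1e-12:
        warnings.warn("groups are not separable; coefficients are near zero")
    else:
        w = w / np.sqrt(scale2)
    grand = X.mean(axis=0)
    constant = -float(w @ grand)
    sm, sf = float(w @ mum + constant), float(w @ muf + constant)
    if prior_weighted_point:
        point = (nm * sm + nf * sf) / (nm + nf)
    else:
        point = 0.5 * (sm + sf)
    return DiscriminantFunction(
        name=name, variables=tuple(variables),
        coefficients=tuple(float(c) for c in w),
        constant=constant, sectioning_point=float(point))


def _apply_report(records: pd.DataFrame, predict, mode: str) -> ClassificationReport:
    sex = records["sex"].str.lower().to_numpy()
    correct = {"male": 0, "female": 0}
    n = {"male": int(np.sum(sex == "male")), "female": int(np.sum(sex == "female"))}
    for i in range(len(records)):
        label = predict(i)
        if label == sex[i]:
            correct[sex[i]] += 1
    rm = 100.0 * correct["male"] / n["male"] if n["male"] else 0.0
    rf = 100.0 * correct["female"] / n["female"] if n["female"] else 0.0
    total = n["male"] + n["female"]
    overall = (n["male"] * rm + n["female"] * rf) / total if total else 0.0
    return ClassificationReport(rate_male=rm, rate_female=rf,
                                rate_overall=overall, n_male=n["male"],
                                n_female=n["female"], mode=mode)


def loocv_classification(records: pd.DataFrame,
                         variables: Sequence[str] | None = None,
                         function: DiscriminantFunction | None = None,
                         tie_policy: str = "indeterminate") -> ClassificationReport:
    """Classification rates by leave-one-out refitting or a fixed function.

    With ``function`` given, each record is simply scored by it
    (mode "resubstitution").  With ``variables`` given, each record is
    classified by a discriminant fit on the remaining n-1 records
    (mode "leave-one-out").
    """
    if (function is None) == (variables is None):
        raise ValueError("pass exactly one of variables= or function=")
    records = records.reset_index(drop=True)
    if function is not None:
        def predict(i):
            return classify_sex(function, records.iloc[i], tie_policy=tie_policy)
        return _apply_report(records, predict, "resubstitution")

    def predict(i):
        rest = records.drop(index=i)
        f = fit_discriminant(rest, variables)
        return classify_sex(f, records.iloc[i], tie_policy=tie_policy)
    return _apply_report(records, predict, "leave-one-out")


def two_sample_t(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t statistic (pooled variance by default) and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        raise ValueError("zero pooled variance; t statistic undefined")
    return t, p


def sex_difference_test(records: pd.DataFrame, variable: str,
                        welch: bool = False):
    """Male-vs-female two-sample t test on one measurement.

    Returns (t, p, n_male, n_female), t oriented as male minus female.
    """
    X, sex = _design(records, [variable])
    male = X[sex == "male", 0]
    female = X[sex == "female", 0]
    t, p = two_sample_t(male, female, welch=welch)
    return t, p, len(male), len(female)
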