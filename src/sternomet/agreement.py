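"""Manual-vs-automatic method agreement statistics.

Per osteometric measurement: signed paired differences (manual - automatic),
mean absolute distance (cm), percentage discrepancy (100 x mean distance /
mean automatic value), a two-sided paired t test, and a fixed-bin difference
histogram (11 equal-width bins spanning the observed difference range, so
bin widths differ between measurements).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementEntry",
    "paired_differences",
    "agreement_summary",
    "difference_histogram",
    "agreement_table",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 11


@dataclass(frozen=True)
class AgreementEntry:
    """Agreement statistics for one measurement."""

    measure: str
    n: int
    manual_mean: float
    manual_sd: float
    automatic_mean: float
    automatic_sd: float
    mean_distance: float
    discrepancy_pct: float
    t_statistic: float | None
    p_value: float | None
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if self.mean_distance < 0 or self.discrepancy_pct < 0:
            raise ValueError("mean distance and discrepancy must be >= 0")
        if int(np.sum(self.counts)) != self.n:
            raise ValueError("histogram counts must sum to n")


def _matched(manual: pd.DataFrame, automatic: pd.DataFrame, measure: str):
    for df, src in ((manual, "manual"), (automatic, "automatic")):
        if measure not in df.columns:
            raise ValueError(f"measure {measure!r} missing from {src} table")
    m = manual[["subject_id", measure]].dropna()
    a = automatic[["subject_id", measure]].dropna()
    merged = m.merge(a, on="subject_id", suffixes=("_man", "_auto"))
    skipped = len(m) + len(a) - 2 * len(merged)
    if skipped:
        logger.info("paired_differences(%s): skipped %d unmatched rows",
                    measure, skipped)
    if merged.empty:
        raise ValueError(f"no matched subject pairs for measure {measure!r}")
    return merged


def paired_differences(manual: pd.DataFrame, automatic: pd.DataFrame,
                       measure: str) -> np.ndarray:
    """Signed per-subject differences manual - automatic (cm)."""
    merged = _matched(manual, automatic, measure)
    return (merged[f"{measure}_man"] - merged[f"{measure}_auto"]).to_numpy(dtype=float)


def difference_histogram(differences: Sequence[float],
                         n_bins: int = DEFAULT_BINS):
    """Equal-width histogram over [min, max]; right-inclusive last bin.

    A degenerate (zero-width) range is widened by a machine-epsilon scaled
    margin so the single populated bin is well defined.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one difference")
    lo, hi = float(d.min()), float(d.max())
    if hi <= lo:
        eps = np.spacing(max(abs(lo), 1.0))
        lo, hi = lo - eps * n_bins, hi + eps * n_bins
    counts, edges = np.histogram(d, bins=n_bins, range=(lo, hi))
    return edges, counts


def agreement_summary(manual: pd.DataFrame, automatic: pd.DataFrame,
                      measure: str, *, denominator: str = "automatic",
                      n_bins: int = DEFAULT_BINS) -> AgreementEntry:
    """Full agreement entry for one measurement.

    ``denominator`` selects the mean used for the discrepancy percentage
    (the automatic mean by default).  The paired t statistic is reported as
    missing when fewer than 2 pairs exist or the differences have zero
    variance.
    """
    if denominator not in ("automatic", "manual"):
        raise ValueError("denominator must be 'automatic' or 'manual'")
    merged = _matched(manual, automatic, measure)
    man = merged[f"{measure}_man"].to_numpy(dtype=float)
    auto = merged[f"{measure}_auto"].to_numpy(dtype=float)
    diffs = man - auto
    n = len(diffs)
    mean_distance = float(np.mean(np.abs(diffs)))
    denom = float(np.mean(auto if denominator == "automatic" else man))
    discrepancy = 100.0 * mean_distance / denom
    t_stat = p_val = None
    if n >= 2 and np.std(diffs, ddof=1) > 0:
        res = stats.ttest_rel(man, auto)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    elif n >= 2 and np.allclose(diffs, 0.0):
        t_stat, p_val = 0.0, 1.0
    edges, counts = difference_histogram(diffs, n_bins)
    return AgreementEntry(
        measure=measure, n=n,
        manual_mean=float(np.mean(man)), manual_sd=float(np.std(man, ddof=1)) if n > 1 else 0.0,
        automatic_mean=float(np.mean(auto)),
        automatic_sd=float(np.std(auto, ddof=1)) if n > 1 else 0.0,
        mean_distance=mean_distance, discrepancy_pct=discrepancy,
        t_statistic=t_stat, p_value=p_val, bin_edges=edges, counts=counts)


def agreement_table(manual: pd.DataFrame, automatic: pd.DataFrame,
                    measures: Sequence[str] = ("CSW1", "CSW2", "B", "MW", "M"),
                    **kwargs) -> pd.DataFrame:
    """DataFrame of agreement statistics, one row per measurement."""
    rows = []
    for m in measures:
        e = agreement_summary(manual, automatic, m, **kwargs)
        rows.append({
            "measure": e.measure, "n": e.n,
            "manual_mean": e.manual_mean, "manual_sd": e.manual_sd,
            "automatic_mean": e.automatic_mean, "automatic_sd": e.automatic_sd,
            "mean_distance": e.mean_distance,
            "discrepancy_pct": e.discrepancy_pct,
            "t": e.t_statistic, "p": e.p_value,
        })
    return pd.DataFrame(rows)
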