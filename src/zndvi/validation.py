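"""Agreement battery between satellite damage classes and field defoliation.

Covers defoliation categorization, binarization into damaged/healthy,
confusion-matrix tallies, the derived rates (precision, sensitivity,
specificity, total accuracy, F1), Cohen's kappa, regression agreement
(R^2, RMSE), and pooled per-stratum reports.  Undefined metrics (zero
denominators) are reported as NaN markers, never silently 0.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from zndvi.indices import CLASS_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "DEFOLIATION_CATEGORIES",
    "AgreementReport",
    "BinarizationRule",
    "ConfusionStats",
    "binarize",
    "categorize_defoliation",
    "cohens_kappa",
    "confusion",
    "join_series_records",
    "metrics",
    "pooled_report",
    "regression_agreement",
]

#: Category name -> (lower, upper] defoliation-percent bound (lower
#: exclusive except the first bin, upper inclusive): None 0-10,
#: Weak >10-25, Medium >25-60, Severe >60-99, Dead >99-100.
DEFOLIATION_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("None", 0.0, 10.0),
    ("Weak", 10.0, 25.0),
    ("Medium", 25.0, 60.0),
    ("Severe", 60.0, 99.0),
    ("Dead", 99.0, 100.0),
)


def categorize_defoliation(pct: float) -> str:
    """Bin a defoliation percentage into its category.

    Boundaries: 10 -> None, 25 -> Weak, 60 -> Medium, 99 -> Severe,
    100 -> Dead.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"defoliation percent out of [0, 100]: {pct}")
    for name, lo, hi in DEFOLIATION_CATEGORIES:
        if pct <= hi:
            return name
    raise AssertionError("unreachable")  # bins cover [0, 100]


@dataclass(frozen=True)
class BinarizationRule:
    """Mapping of 5-way labels to damaged(positive)/healthy(negative).

    Defaults: satellite positive iff class code in {0 severe damage,
    1 damage}; field positive iff category implies defoliation > 25%
    (Medium, Severe, Dead).  The rule is serialized into every report.
    """

    sat_positive_classes: frozenset[int] = frozenset({0, 1})
    field_positive_categories: frozenset[str] = frozenset({"Medium", "Severe", "Dead"})

    def to_dict(self) -> dict:
        return {
            "sat_positive_classes": sorted(self.sat_positive_classes),
            "field_positive_categories": sorted(self.field_positive_categories),
        }


def binarize(
    sat_class: int, field_category: str, rule: BinarizationRule | None = None
) -> tuple[bool, bool]:
    """(satellite positive, field positive) under the rule."""
    rule = rule or BinarizationRule()
    if sat_class < 0 or sat_class >= len(CLASS_NAMES):
        raise ValueError(f"undefined satellite class code {sat_class}")
    if field_category not in {c[0] for c in DEFOLIATION_CATEGORIES}:
        raise ValueError(f"unknown defoliation category {field_category!r}")
    return (
        sat_class in rule.sat_positive_classes,
        field_category in rule.field_positive_categories,
    )


@dataclass(frozen=True)
class ConfusionStats:
    """Four confusion components plus (optionally) the derived rates.

    Components may be raw counts or normalized rates; derived fields are
    NaN until :func:`metrics` fills them, and NaN where undefined.
    """

    tp: float
    fp: float
    fn: float
    tn: float
    precision: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    total_accuracy: float = math.nan
    f1: float = math.nan
    kappa: float = math.nan

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    pairs: Iterable[tuple[bool, bool]], normalize: str = "none"
) -> ConfusionStats:
    """Tally (predicted positive, actual positive) pairs.

    ``normalize``: "none" for raw counts, "actual" to divide TP/FN by
    actual positives and FP/TN by actual negatives, "total" to divide
    every cell by the pair count.
    """
    tp = fp = fn = tn = 0
    n = 0
    for pred, actual in pairs:
        n += 1
        if pred and actual:
            tp += 1
        elif pred and not actual:
            fp += 1
        elif not pred and actual:
            fn += 1
        else:
            tn += 1
    if n == 0:
        raise ValueError("confusion requires at least one pair")
    if normalize == "none":
        return ConfusionStats(tp=tp, fp=fp, fn=fn, tn=tn)
    if normalize == "total":
        return ConfusionStats(tp=tp / n, fp=fp / n, fn=fn / n, tn=tn / n)
    if normalize == "actual":
        pos = tp + fn
        neg = fp + tn
        return ConfusionStats(
            tp=tp / pos if pos else math.nan,
            fn=fn / pos if pos else math.nan,
            fp=fp / neg if neg else math.nan,
            tn=tn / neg if neg else math.nan,
        )
    raise ValueError(f"unknown normalization {normalize!r}")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionStats) -> ConfusionStats:
    """Fill the five derived rates from the four components.

    precision = TP/(TP+FP); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); total accuracy = (TP+TN)/total;
    F1 = 2TP/(2TP+FP+FN).  Zero denominators give NaN markers.
    """
    return replace(
        c,
        precision=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        total_accuracy=_ratio(c.tp + c.tn, c.total),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def cohens_kappa(pairs: Iterable[tuple[object, object]]) -> float:
    """Chance-corrected agreement for two labelings over any label set.

    k = (p_o - p_e) / (1 - p_e) with p_e from the marginal label
    frequencies of each rater.  p_e = 1 exactly -> NaN (undefined).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("cohens_kappa requires at least one pair")
    n = len(pairs)
    a_marg: Counter = Counter(a for a, _ in pairs)
    b_marg: Counter = Counter(b for _, b in pairs)
    p_o = sum(1 for a, b in pairs if a == b) / n
    labels = set(a_marg) | set(b_marg)
    p_e = sum((a_marg[l] / n) * (b_marg[l] / n) for l in labels)
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_counts(tp: float, fp: float, fn: float, tn: float) -> float:
    """Binary kappa straight from 2x2 cell counts."""
    n = tp + fp + fn + tn
    if n <= 0:
        raise ValueError("empty confusion table")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) / n) * ((tp + fn) / n) + ((fn + tn) / n) * ((fp + tn) / n)
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def regression_agreement(
    sat_values: Sequence[float],
    field_defoliation_pct: Sequence[float],
    sign: float = -1.0,
) -> tuple[float, float]:
    """OLS of field defoliation % on (sign * z); returns (R^2, RMSE)
    with RMSE in defoliation-percent units.  The default sign flips z so
    larger predictor means more damage."""
    from zndvi.climate import fit_linear

    x = sign * np.asarray(sat_values, dtype=float)
    y = np.asarray(field_defoliation_pct, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("regression_agreement needs >= 3 complete pairs")
    res = fit_linear(x[keep], y[keep])
    return res.r_squared, res.rmse


@dataclass
class AgreementReport:
    """Confusion components, derived rates, kappa and regression metrics
    for one stratum."""

    stratum: str
    n: int
    n_missing: int
    stats: ConfusionStats
    r_squared: float
    rmse: float
    rule: BinarizationRule

    def to_row(self) -> dict:
        s = self.stats
        return {
            "stratum": self.stratum,
            "n": self.n,
            "missing": self.n_missing,
            "kappa": s.kappa,
            "tp": s.tp,
            "fp": s.fp,
            "fn": s.fn,
            "tn": s.tn,
            "precision": s.precision,
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "total_accuracy": s.total_accuracy,
            "f1": s.f1,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
        }


def join_series_records(series, records) -> pd.DataFrame:
    """Join extracted plot series with field records on (plot_id, year).

    Returns one row per plot-year with columns plot_id, level, year,
    z_mean, sat_class, defoliation_pct, defoliation_category.
    """
    from zndvi.plots import records_to_frame

    rows = []
    for s in series:
        for y, z in s.z_mean.items():
            rows.append(
                {"plot_id": s.plot_id, "level": s.level, "year": y,
                 "z_mean": z, "sat_class": s.cls[y]}
            )
    left = pd.DataFrame(rows)
    right = records_to_frame(records)[
        ["plot_id", "year", "defoliation_pct", "defoliation_category"]
    ]
    return left.merge(right, on=["plot_id", "year"], how="inner")


def _stratum_report(
    name: str, df: pd.DataFrame, rule: BinarizationRule
) -> AgreementReport | None:
    missing = int(((df["sat_class"] < 0) | df["defoliation_pct"].isna()).sum())
    ok = df[(df["sat_class"] >= 0) & df["defoliation_pct"].notna()]
    if len(ok) < 1:
        log.info("stratum %s skipped: no complete pairs (%d missing)", name, missing)
        return None
    pairs = [
        binarize(int(sc), cat, rule)
        for sc, cat in zip(ok["sat_class"], ok["defoliation_category"])
    ]
    stats = metrics(confusion(pairs))
    stats = replace(stats, kappa=cohens_kappa(pairs))
    try:
        r2, rmse = regression_agreement(
            ok["z_mean"].to_numpy(), ok["defoliation_pct"].to_numpy()
        )
    except ValueError:
        r2, rmse = math.nan, math.nan
    return AgreementReport(
        stratum=name, n=len(ok), n_missing=missing, stats=stats,
        r_squared=r2, rmse=rmse, rule=rule,
    )


def pooled_report(
    joined: pd.DataFrame,
    strata: str = "year",
    rule: BinarizationRule | None = None,
) -> list[AgreementReport]:
    """Per-stratum agreement reports plus a grand pooled row.

    ``strata`` is one of "year", "plot", "level".  Missing plot-years
    (unclassified satellite or absent field value) are excluded from the
    tallies and counted per stratum.
    """
    rule = rule or BinarizationRule()
    key = {"year": "year", "plot": "plot_id", "level": "level"}.get(strata)
    if key is None:
        raise ValueError(f"unknown strata {strata!r}")
    reports: list[AgreementReport] = []
    for value, group in joined.groupby(key, sort=True):
        rep = _stratum_report(str(value), group, rule)
        if rep is not None:
            reports.append(rep)
    pooled = _stratum_report("pooled", joined, rule)
    if pooled is not None:
        reports.append(pooled)
    return reports
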