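"""Correlation, residual and consensus analyses.

The inter-medium agreement statistics are squared Pearson correlations of
the scatter (not regression through the origin). Lipophilicity strata are
half-open intervals on predicted logD at pH 6.5: [-inf, 3), [3, 4),
[4, inf) by default. The consensus predictor is the unweighted arithmetic
mean of two models' log-solubility outputs; by convexity of squared error
its RMSE never exceeds the root-mean of the two models' squared RMSEs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Medium, SolubilityDataset, paired_values

__all__ = [
    "pearson_r2",
    "CorrelationReport",
    "stratified_correlation",
    "consensus_average",
    "ConsensusPrediction",
    "residual_report",
    "fold_range_claim",
]


class EvaluationError(ValueError):
    pass


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EvaluationError("inputs must be equal-length vectors")
    if x.size < 3:
        raise EvaluationError("need at least 3 points")
    if np.var(x) < 1e-15 or np.var(y) < 1e-15:
        raise EvaluationError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


@dataclass(frozen=True)
class CorrelationReport:
    """r^2 between two media within one lipophilicity stratum."""

    medium_a: Medium
    medium_b: Medium
    stratum: str                # "all", "logd_lt3", "logd_3to4", "logd_gt4", ...
    n: int
    r2: float | None            # None when the stratum has < 3 pairs
    names: tuple[str, ...]


def _stratum_label(lo: float, hi: float) -> str:
    if math.isinf(lo) and math.isinf(hi):
        return "all"
    if math.isinf(lo):
        return f"logd_lt{hi:g}"
    if math.isinf(hi):
        return f"logd_gt{lo:g}"
    return f"logd_{lo:g}to{hi:g}"


def stratified_correlation(
    ds: SolubilityDataset, medium_a: Medium | str, medium_b: Medium | str,
    logd_breaks: tuple[float, ...] = (3.0, 4.0),
) -> list[CorrelationReport]:
    """Global and per-stratum r^2 over complete cases of two media.

    Strata are half-open: with breaks (3, 4) they are [-inf,3), [3,4),
    [4,inf). A stratum with fewer than 3 pairs is reported with
    ``r2=None`` rather than raising. The first report is always the
    unstratified ("all") one.
    """
    med_a, med_b = Medium.coerce(medium_a), Medium.coerce(medium_b)
    xs, ys, names = paired_values(ds, med_a, med_b)
    logd = {r.name: r.logd65 for r in ds}
    missing = [n for n in names if logd[n] is None]
    if missing:
        raise EvaluationError(f"logD missing for: {', '.join(missing)}")
    edges = (-math.inf, *sorted(logd_breaks), math.inf)
    reports = [CorrelationReport(med_a, med_b, "all", len(names),
                                 pearson_r2(xs, ys), tuple(names))]
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = [i for i, n in enumerate(names) if lo <= logd[n] < hi]
        sub_x = [xs[i] for i in idx]
        sub_y = [ys[i] for i in idx]
        r2 = pearson_r2(sub_x, sub_y) if len(idx) >= 3 else None
        reports.append(CorrelationReport(
            med_a, med_b, _stratum_label(lo, hi), len(idx), r2,
            tuple(names[i] for i in idx)))
    return reports


@dataclass(frozen=True)
class ConsensusPrediction:
    name: str
    pred_a: float
    pred_b: float
    observed: float | None = None

    @property
    def consensus(self) -> float:
        return (self.pred_a + self.pred_b) / 2.0

    def residual(self) -> float | None:
        return None if self.observed is None else self.consensus - self.observed


def consensus_average(pred_a: pd.Series, pred_b: pd.Series,
                      observed: pd.Series | None = None) -> list[ConsensusPrediction]:
    """Unweighted per-compound average of two prediction series.

    The series are indexed by compound name and must cover the same
    compounds; a coverage mismatch lists the offending names.
    """
    only_a = sorted(set(pred_a.index) - set(pred_b.index))
    only_b = sorted(set(pred_b.index) - set(pred_a.index))
    if only_a or only_b:
        raise EvaluationError(
            f"prediction coverage mismatch; only in A: {only_a}, only in B: {only_b}")
    out = []
    for name in pred_a.index:
        obs = None
        if observed is not None and name in observed.index:
            v = observed[name]
            obs = None if pd.isna(v) else float(v)
        out.append(ConsensusPrediction(str(name), float(pred_a[name]),
                                       float(pred_b[name]), obs))
    return out


def residual_report(predictions: pd.Series, observations: pd.Series,
                    threshold: float = 1.0) -> pd.DataFrame:
    """Compounds mis-predicted by at least ``threshold`` log10 units.

    Returns a frame (name, observed, predicted, residual) sorted by
    |residual| descending; residual = predicted - observed, so positive
    means over-prediction of solubility.
    """
    common = [n for n in predictions.index if n in observations.index]
    rows = []
    for name in common:
        resid = float(predictions[name]) - float(observations[name])
        if abs(resid) >= threshold:
            rows.append({"name": name, "observed": float(observations[name]),
                         "predicted": float(predictions[name]), "residual": resid})
    frame = pd.DataFrame(rows, columns=["name", "observed", "predicted", "residual"])
    if not frame.empty:
        frame = frame.reindex(
            frame.residual.abs().sort_values(ascending=False, kind="stable").index)
        frame = frame.reset_index(drop=True)
    return frame


def fold_range_claim(ds: SolubilityDataset) -> dict[str, float]:
    """Per-medium solubility span as a linear fold range, 2 significant figures."""
    from .dataset import summarize

    out = {}
    for med in Medium:
        try:
            s = summarize(ds, med)
        except Exception:
            continue
        fr = s.fold_range
        out[med.value] = float(f"{fr:.2g}") if fr > 0 else fr
    return out
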