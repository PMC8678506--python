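"""Model evaluation: ranking metrics, bootstrap CIs, horizon tables, alarms.

AUROC is the probability that a random positive outranks a random negative
(ties half credit, the Mann-Whitney convention); AUPRC and F1 are delegated
to scikit-learn.  Confidence intervals are percentile bootstrap over 1,000
resamples drawn at the *patient* level by default, respecting within-patient
correlation of windows (window-level resampling is available by flag).

The horizon report collects (model x disease x horizon) rows of
AUROC/AUPRC/F1 with 95% CIs — the per-horizon performance table — and the
alarm sweep measures event-level precision/recall of threshold alerts raised
in the window one horizon ahead of ground-truth onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = [
    "EvalReport",
    "BootstrapResult",
    "auroc",
    "auprc",
    "f1_at_threshold",
    "precision_recall_at_threshold",
    "bootstrap_ci",
    "alarm_metrics",
    "horizon_report",
    "report_table",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.95, 0.05), 2)) + (0.7,)


class SingleClassError(ValueError):
    """Metric undefined because only one class is present."""


def _check_two_class(labels: np.ndarray) -> None:
    if len(labels) == 0 or labels.min() == labels.max():
        raise SingleClassError("metric undefined: only one class present")


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_class(labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    labels = np.asarray(labels, dtype=float)
    _check_two_class(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def precision_recall_at_threshold(scores, labels, threshold: float):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pred = scores >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    return precision, recall


def f1_at_threshold(scores, labels, threshold: float = 0.5) -> float:
    """Harmonic mean of precision and recall at a decision threshold."""
    _check_two_class(np.asarray(labels, dtype=float))
    p, r = precision_recall_at_threshold(scores, labels, threshold)
    if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


class BootstrapResult(NamedTuple):
    point: float
    low: float
    high: float
    n_skipped: int


def _resample_indices(groups: Optional[np.ndarray], n: int, rng) -> np.ndarray:
    """Draw one bootstrap resample: patient blocks when groups are given."""
    if groups is None:
        return rng.integers(0, n, size=n)
    uniq, inv = np.unique(groups, return_inverse=True)
    members = [np.nonzero(inv == g)[0] for g in range(len(uniq))]
    chosen = rng.integers(0, len(uniq), size=len(uniq))
    return np.concatenate([members[g] for g in chosen])


def bootstrap_ci(metric_fn: Callable, scores, labels, groups=None,
                 n_resamples: int = 1000, level: float = 0.95,
                 seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap CI; deterministic given seed.

    Resamples are drawn at the patient level when ``groups`` is given.
    Resamples with a single class are skipped and counted; more than 10%
    skips triggers a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    groups = None if groups is None else np.asarray(groups)
    point = metric_fn(scores, labels)
    rng = np.random.default_rng(seed)
    uniq = None
    if groups is not None:
        uniq, inv = np.unique(groups, return_inverse=True)
        members = [np.nonzero(inv == g)[0] for g in range(len(uniq))]
    vals = []
    skipped = 0
    for _ in range(n_resamples):
        if groups is None:
            idx = rng.integers(0, len(scores), size=len(scores))
        else:
            chosen = rng.integers(0, len(uniq), size=len(uniq))
            idx = np.concatenate([members[g] for g in chosen])
        try:
            vals.append(metric_fn(scores[idx], labels[idx]))
        except SingleClassError:
            skipped += 1
    if skipped > 0.1 * n_resamples:
        warnings.warn(f"{skipped}/{n_resamples} bootstrap resamples were "
                      "single-class and skipped")
    if not vals:
        return BootstrapResult(point, np.nan, np.nan, skipped)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(float(point), float(lo), float(hi), skipped)


@dataclass
class EvalReport:
    """Metric table (long format) plus an optional threshold sweep."""

    frame: pd.DataFrame
    threshold_sweep: Optional[pd.DataFrame] = None

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")

    def sweep_to_csv(self, path) -> None:
        if self.threshold_sweep is not None:
            self.threshold_sweep.to_csv(path, index=False, float_format="%.6f")


def horizon_report(prediction_sets: Sequence, n_resamples: int = 1000,
                   level: float = 0.95, seed: int = 0,
                   patient_bootstrap: bool = True,
                   f1_threshold: float = 0.5) -> EvalReport:
    """AUROC/AUPRC/F1 with bootstrap CIs per (model, disease, horizon).

    Cells whose metric is undefined (single-class test labels) are reported
    as NaN with a reason, never as zero.
    """
    metrics = {
        "AUROC": auroc,
        "AUPRC": auprc,
        "F1": lambda s, l: f1_at_threshold(s, l, f1_threshold),
    }
    rows = []
    for ps in prediction_sets:
        f = ps.frame[ps.frame["label"].notna()]
        for (dis, h), sub in sorted(f.groupby(["disease", "horizon_h"], sort=True)):
            scores = sub["risk"].to_numpy()
            labels = sub["label"].to_numpy()
            groups = sub["patient_id"].to_numpy() if patient_bootstrap else None
            for mname, fn in metrics.items():
                try:
                    res = bootstrap_ci(fn, scores, labels, groups=groups,
                                       n_resamples=n_resamples, level=level,
                                       seed=seed)
                    point, lo, hi, reason = res.point, res.low, res.high, ""
                except SingleClassError as exc:
                    point = lo = hi = np.nan
                    reason = str(exc)
                rows.append({
                    "model": ps.model_id, "disease": dis, "horizon_h": h,
                    "metric": mname, "point": point, "ci_low": lo, "ci_high": hi,
                    "n_windows": len(labels), "n_positive": int(labels.sum()),
                    "reason": reason,
                })
    frame = pd.DataFrame(rows).sort_values(
        ["model", "disease", "horizon_h", "metric"]).reset_index(drop=True)
    return EvalReport(frame)


def report_table(report: EvalReport, metric: str = "AUROC") -> pd.DataFrame:
    """Wide per-horizon table: rows = models, columns = (disease, horizon)."""
    f = report.frame[report.frame["metric"] == metric]
    return f.pivot_table(index="model", columns=["disease", "horizon_h"],
                         values="point")


def alarm_metrics(prediction_set, timelines: Mapping, disease: str,
                  horizon_h: float = 8.0, sampling_window_h: float = 24.0,
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Event-level alarm sweep.

    An alert at threshold thr is a risk >= thr predicted for the window one
    horizon ahead.  Event recall is the fraction of ground-truth onset events
    (first positive window per patient) for which any alert targeted the
    onset window; precision is the fraction of alerts whose targeted window
    was truly positive.  Window-level sensitivity/specificity at each
    threshold are reported alongside.  Precision is NaN when no alert fired.
    """
    f = prediction_set.frame
    f = f[(f["disease"] == disease) & (f["horizon_h"] == horizon_h)
          & f["label"].notna()].copy()
    f["target_time_h"] = f["window_start_h"] + sampling_window_h + horizon_h

    events = {}  # patient -> (event_start, event_end)
    for pid, tl in timelines.items():
        w = tl.onset_window(disease)
        if w is not None:
            events[pid] = (w * tl.window_len_h, (w + 1) * tl.window_len_h)

    rows = []
    scores = f["risk"].to_numpy()
    labels = f["label"].to_numpy()
    for thr in thresholds:
        alerts = f[f["risk"] >= thr]
        precision = float((alerts["label"] == 1).mean()) if len(alerts) else np.nan
        hits = 0
        for pid, (ev_lo, ev_hi) in events.items():
            sub = alerts[(alerts["patient_id"] == pid)
                         & (alerts["target_time_h"] >= ev_lo)
                         & (alerts["target_time_h"] < ev_hi)]
            if len(sub):
                hits += 1
        recall = hits / len(events) if events else np.nan
        pred = scores >= thr
        pos, neg = labels == 1, labels == 0
        sens = float(pred[pos].mean()) if pos.any() else np.nan
        spec = float((~pred[neg]).mean()) if neg.any() else np.nan
        rows.append({"threshold": float(thr), "n_alerts": int(len(alerts)),
                     "precision": precision, "recall": recall,
                     "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)
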