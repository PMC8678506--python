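"""Ranking metrics, bootstrap confidence intervals, alarm sweeps, reports."""

import numpy as np
import pandas as pd
import pytest

from coagcast.evaluation import (alarm_metrics, auprc, auroc,
                                 bootstrap_ci, f1_at_threshold, horizon_report,
                                 precision_recall_at_threshold, report_table)
from coagcast.models import PredictionSet
from coagcast.scoring import LabelEntry, LabelTimeline

from _oracles import auroc_pair_counting


@pytest.mark.parametrize("scores,labels,expected", [
    ([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], 1.0),
    ([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0], 0.75),
    ([0.9, 0.8, 0.3, 0.2], [0, 0, 1, 1], 0.0),
    ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),   # all ties -> half credit
])
def test_auroc_worked_examples(scores, labels, expected):
    assert auroc(scores, labels) == pytest.approx(expected)


def test_auroc_matches_pair_counting_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(4, 50)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels))


def test_single_class_metrics_raise():
    with pytest.raises(ValueError, match="one class"):
        auroc([0.1, 0.2], [1, 1])
    with pytest.raises(ValueError):
        auprc([0.1, 0.2], [0, 0])


def test_auprc_and_f1_basics():
    assert auprc([0.9, 0.8, 0.2], [1, 1, 0]) == pytest.approx(1.0)
    assert f1_at_threshold([0.9, 0.1], [1, 0], 0.5) == pytest.approx(1.0)
    p, r = precision_recall_at_threshold([0.9, 0.6, 0.4], [1, 0, 1], 0.0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(2 / 3)   # precision equals prevalence at thr 0


def test_f1_identity_on_random_confusion_tables():
    rng = np.random.default_rng(1)
    for _ in range(50):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.min() == labels.max():
            continue
        p, r = precision_recall_at_threshold(scores, labels, 0.5)
        f1 = f1_at_threshold(scores, labels, 0.5)
        if np.isfinite(p) and p + r > 0:
            assert f1 == pytest.approx(2 * p * r / (p + r))


def test_bootstrap_deterministic_and_ordered():
    rng = np.random.default_rng(2)
    scores = rng.uniform(size=300)
    labels = (scores + rng.normal(0, 0.3, 300) > 0.5).astype(int)
    groups = np.repeat(np.arange(30), 10)
    a = bootstrap_ci(auroc, scores, labels, groups=groups, seed=7)
    b = bootstrap_ci(auroc, scores, labels, groups=groups, seed=7)
    assert a == b
    assert a.low <= a.point <= a.high


def test_bootstrap_constant_metric_collapses_interval():
    res = bootstrap_ci(lambda s, l: 0.42, [1, 2, 3], [0, 1, 0], n_resamples=50)
    assert res.low == res.point == res.high == 0.42


def test_bootstrap_width_shrinks_with_n():
    def width(n):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=n)
        labels = (scores + rng.normal(0, 0.5, n) > 0.5).astype(int)
        r = bootstrap_ci(auroc, scores, labels, n_resamples=200, seed=1)
        return r.high - r.low
    assert width(10_000) < width(100)


def test_bootstrap_resamples_whole_patient_blocks():
    groups = np.repeat(np.arange(20), 5)
    labels = np.tile([1, 0, 0, 1, 0], 20)
    scores = np.arange(100, dtype=float)  # score encodes the window index
    calls = []

    def spy(s, l):
        calls.append(s.astype(int))
        return 0.5

    bootstrap_ci(spy, scores, labels, groups=groups, n_resamples=20, seed=0)
    assert len(calls) == 21  # point estimate + resamples
    for idx in calls[1:]:
        per_patient = np.bincount(idx, minlength=100).reshape(20, 5)
        # windows of a patient appear all together, with equal multiplicity
        assert np.all(per_patient == per_patient[:, :1])


def _pred_set(rows):
    return PredictionSet("m", pd.DataFrame(rows, columns=[
        "model", "patient_id", "window_start_h", "disease", "horizon_h",
        "risk", "label"]))


def _timeline(labels):
    return LabelTimeline("P1", 8.0, [
        LabelEntry(i, l, l, "observed") for i, l in enumerate(labels)])


def test_alarm_metrics_oracle_risks():
    # onset in window 5 ([40, 48) h); a window ending at 32 h predicts it at
    # the 8 h horizon (target time 40 h)
    tl = _timeline([0, 0, 0, 0, 0, 1, 1])
    rows = [("m", "P1", 8.0, "DIC", 8.0, 1.0, 1.0),
            ("m", "P1", 0.0, "DIC", 8.0, 0.0, 0.0)]
    sweep = alarm_metrics(_pred_set(rows), {"P1": tl}, "DIC", thresholds=(0.5,))
    row = sweep.iloc[0]
    assert row.precision == 1.0 and row.recall == 1.0


def test_alarm_metrics_all_zero_risks():
    tl = _timeline([0, 0, 0, 0, 0, 1])
    rows = [("m", "P1", 8.0, "DIC", 8.0, 0.0, 1.0)]
    sweep = alarm_metrics(_pred_set(rows), {"P1": tl}, "DIC", thresholds=(0.5,))
    assert sweep.iloc[0].recall == 0.0
    assert np.isnan(sweep.iloc[0].precision)


def test_alarm_recall_non_increasing_in_threshold():
    rng = np.random.default_rng(5)
    tl = _timeline([0, 0, 0, 0, 0, 1, 1])
    rows = [("m", "P1", float(s), "DIC", 8.0, rng.uniform(), float(l))
            for s, l in [(0.0, 0), (8.0, 1), (16.0, 1)]]
    sweep = alarm_metrics(_pred_set(rows), {"P1": tl}, "DIC")
    rec = sweep.sort_values("threshold")["recall"].to_numpy()
    assert np.all(np.diff(rec) <= 1e-12)


def test_horizon_report_deterministic_bytes(tmp_path, encoded_small):
    rng = np.random.default_rng(6)
    rows = [("m", f"P{i % 7}", 0.0, "DIC", 8.0, rng.uniform(), float(i % 2))
            for i in range(60)]
    ps = _pred_set(rows)
    paths = []
    for tag in ("a", "b"):
        rep = horizon_report([ps], n_resamples=100, seed=3)
        p = tmp_path / f"{tag}.csv"
        rep.to_csv(p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_horizon_report_single_class_cell_reported_absent():
    rows = [("m", "P1", 0.0, "DIC", 8.0, 0.4, 1.0),
            ("m", "P2", 0.0, "DIC", 8.0, 0.6, 1.0)]
    rep = horizon_report([_pred_set(rows)], n_resamples=10)
    sub = rep.frame[rep.frame["metric"] == "AUROC"].iloc[0]
    assert np.isnan(sub.point) and "one class" in sub.reason


def test_report_table_layout():
    rows = [("m", "P1", 0.0, "DIC", 8.0, 0.9, 1.0),
            ("m", "P2", 0.0, "DIC", 8.0, 0.1, 0.0)]
    rep = horizon_report([_pred_set(rows)], n_resamples=10)
    table = report_table(rep)
    assert table.loc["m", ("DIC", 8.0)] == pytest.approx(1.0)
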