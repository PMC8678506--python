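"""Shared fixtures: small synthetic cohorts and hand-built toy windows."""

from types import SimpleNamespace

import numpy as np
import pytest

from coagcast.cohort import CohortConfig, generate_cohort
from coagcast.encoding import (EncodingConfig, Normalizer, WindowTensor,
                               compute_intervals, encode_cohort)
from coagcast.pipeline import split_patients
from coagcast.scoring import label_streams


@pytest.fixture(scope="session")
def small_cohort():
    """60 patients with short stays; enough SIC/DIC events for label tests."""
    cfg = CohortConfig(n_patients=60, max_stay_h=120.0, seed=11)
    streams, trajs = generate_cohort(cfg)
    stays = {t.patient_id: t.stay_h for t in trajs}
    timelines = label_streams(streams, stays=stays)
    return SimpleNamespace(config=cfg, streams=streams, trajectories=trajs,
                           stays=stays, timelines=timelines)


@pytest.fixture(scope="session")
def encoded_small(small_cohort):
    """Patient-split, normalized, windowed view of the small cohort."""
    enc = EncodingConfig(horizons_h=(8.0, 48.0))
    ids = [s.patient_id for s in small_cohort.streams]
    train_ids, valid_ids, test_ids = split_patients(ids, seed=5)
    by = {s.patient_id: s for s in small_cohort.streams}
    norm = Normalizer.fit([by[p] for p in train_ids], enc.variables)
    tl = small_cohort.timelines
    return SimpleNamespace(
        enc=enc, normalizer=norm, variables=norm.kept(enc.variables),
        streams=small_cohort.streams, timelines=tl,
        train=encode_cohort([by[p] for p in train_ids], tl, enc, norm),
        valid=encode_cohort([by[p] for p in valid_ids], tl, enc, norm),
        test=encode_cohort([by[p] for p in test_ids], tl, enc, norm),
        train_ids=train_ids, valid_ids=valid_ids, test_ids=test_ids,
    )


def make_toy_window(rng, pid: str, label_fn, D: int = 2, T: int = 3,
                    horizon: float = 8.0, timestamps=None) -> WindowTensor:
    """Hand-built fully-observed window whose target is a function of x."""
    ts = np.sort(rng.uniform(0.0, 24.0, T)) if timestamps is None \
        else np.asarray(timestamps, dtype=float)
    x = rng.uniform(0.0, 1.0, size=(T, D))
    m = np.ones((T, D))
    steps = np.diff(np.concatenate([[0.0], ts]))
    delta = compute_intervals(ts, m)
    label = int(label_fn(x))
    return WindowTensor(
        patient_id=pid, window_start_h=0.0, window_len_h=24.0,
        timestamps=ts, x=x, m=m, steps=steps, delta=delta,
        targets={horizon: (label, label)},
        delta_end=24.0 - ts[-1] + delta[-1] * 0,
    )


def toy_dataset(n: int, seed: int, label_fn, D: int = 2, T: int = 3):
    rng = np.random.default_rng(seed)
    # one observation per 8 h grid cell, so the discretized view captures
    # every observation and the label is recoverable by every model family
    ts = [2.0, 10.0, 18.0] if T == 3 else None
    return [make_toy_window(rng, f"T{i:04d}", label_fn, D, T, timestamps=ts)
            for i in range(n)]


@pytest.fixture(scope="session")
def one_signal():
    """Cohort where PLT alone drives the labels (other variables sit at their
    healthy means; sampling uncoupled from severity) with a trained XGBoost
    head for SIC at the 8 h horizon."""
    from coagcast.models import train_tabular_baselines

    cfg = CohortConfig(n_patients=250, max_stay_h=120.0, seed=17,
                       severity_sampling_coupling=0.0, signal_variables=("PLT",))
    streams, trajs = generate_cohort(cfg)
    timelines = label_streams(streams, stays={t.patient_id: t.stay_h
                                              for t in trajs})
    enc = EncodingConfig(horizons_h=(8.0,))
    train_ids, valid_ids, test_ids = split_patients(
        [s.patient_id for s in streams], seed=2)
    by = {s.patient_id: s for s in streams}
    norm = Normalizer.fit([by[p] for p in train_ids], enc.variables)
    variables = norm.kept(enc.variables)
    train_w = encode_cohort([by[p] for p in train_ids + valid_ids],
                            timelines, enc, norm)
    test_streams = [by[p] for p in test_ids]
    model = train_tabular_baselines(train_w, enc, variables, "xgboost",
                                    diseases=("SIC",), seed=0)
    test_w = encode_cohort(test_streams, timelines, enc, norm)
    return dict(model=model, streams=test_streams, timelines=timelines,
                enc=enc, norm=norm, variables=variables, test_windows=test_w)


@pytest.fixture()
def toy_separable():
    """Linearly separable toy: label = 1 iff mean of variable 0 > 0.5."""
    return toy_dataset(300, 42, lambda x: x[:, 0].mean() > 0.5)


@pytest.fixture()
def toy_nonlinear():
    """XOR-style threshold interaction that linear models cannot express."""
    return toy_dataset(500, 43, lambda x: (x[:, 0].mean() > 0.5) ^ (x[:, 1].mean() > 0.5))
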