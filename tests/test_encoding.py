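"""Mask/interval encoding, normalization, windowing, discretization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coagcast.cohort import CohortConfig, LabEvent, LabEventStream, generate_cohort
from coagcast.encoding import (EncodingConfig, Normalizer, build_windows,
                               compute_intervals, compute_mask,
                               discretize_for_tabular, read_windows,
                               tabular_feature_names, write_windows)
from coagcast.scoring import label_streams

from _oracles import backward_scan_intervals


def test_mask_definition():
    vals = np.array([[1.0, np.nan, 3.0], [np.nan, np.nan, np.nan], [1.0, 1.0, 1.0]])
    m = compute_mask(vals)
    assert m.tolist() == [[1, 0, 1], [0, 0, 0], [1, 1, 1]]


@pytest.mark.parametrize("s,m,expected", [
    ([0, 3, 7], [1, 0, 1], [0, 3, 7]),       # third entry: (7-3)+3
    ([0, 2, 5], [1, 1, 1], [0, 2, 3]),
    ([4.0], [1], [0.0]),
])
def test_interval_recurrence_worked_examples(s, m, expected):
    delta = compute_intervals(np.array(s, float), np.array(m, float)[:, None])
    assert delta[:, 0].tolist() == expected


def test_interval_rejects_unsorted_timestamps():
    with pytest.raises(ValueError):
        compute_intervals(np.array([0.0, 2.0, 1.0]), np.ones((3, 1)))


@settings(derandomize=True, max_examples=100)
@given(st.integers(0, 10_000))
def test_interval_matches_backward_scan(seed):
    rng = np.random.default_rng(seed)
    T, D = rng.integers(1, 15), rng.integers(1, 5)
    s = np.sort(rng.uniform(0, 48, T))
    m = (rng.uniform(size=(T, D)) < 0.5).astype(float)
    np.testing.assert_allclose(compute_intervals(s, m), backward_scan_intervals(s, m))


def test_normalizer_maps_training_extremes_to_unit_interval():
    events = [LabEvent(float(i), "PLT", v, "") for i, v in enumerate([100, 200, 300])]
    norm = Normalizer.fit([LabEventStream("P1", events)], ["PLT"])
    assert norm.transform("PLT", 100) == 0.0
    assert norm.transform("PLT", 300) == 1.0
    assert norm.transform("PLT", 200) == 0.5
    assert norm.transform("PLT", 500) == 1.0  # clamps above training max


def test_normalizer_drops_constant_variable_with_warning():
    events = [LabEvent(float(i), "PLT", 100.0, "") for i in range(3)]
    with pytest.warns(UserWarning, match="dropped"):
        norm = Normalizer.fit([LabEventStream("P1", events)], ["PLT", "INR"])
    assert norm.kept(["PLT", "INR"]) == ()


def test_normalizer_json_roundtrip():
    norm = Normalizer({"PLT": (10.0, 300.0)}, dropped=("INR",))
    back = Normalizer.from_json(norm.to_json())
    assert back.stats == norm.stats and back.dropped == norm.dropped


def _simple_setup(stay_h=72.0, events=None):
    from coagcast.scoring import LabelEntry, LabelTimeline
    if events is None:
        events = [(t, "PLT", 200.0) for t in np.arange(1.0, stay_h, 6.0)]
    stream = LabEventStream(
        "P1", [LabEvent(t, v, x, "") for t, v, x in sorted(events)])
    n = int(stay_h // 8)
    tl = LabelTimeline("P1", 8.0, [LabelEntry(w, 0, 0, "observed") for w in range(n)])
    norm = Normalizer({"PLT": (50.0, 400.0), "INR": (0.8, 3.0)})
    cfg = EncodingConfig(variables=("PLT", "INR"), horizons_h=(8.0,))
    return stream, tl, cfg, norm


def test_window_count_arithmetic():
    stream, tl, cfg, norm = _simple_setup(72.0)
    wins = build_windows(stream, tl, cfg, norm, drop_untargeted=False)
    assert len(wins) == 7
    assert [w.window_start_h for w in wins] == [0.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0]


@settings(derandomize=True, max_examples=30)
@given(st.floats(24.0, 200.0))
def test_window_count_formula(stay):
    stay = 8.0 * int(stay // 8)  # timeline covers whole windows
    stream, tl, cfg, norm = _simple_setup(stay)
    wins = build_windows(stream, tl, cfg, norm, drop_untargeted=False)
    assert len(wins) == int((stay - 24.0) // 8.0) + 1


def test_boundary_event_belongs_to_next_window():
    events = [(24.0, "PLT", 200.0), (1.0, "PLT", 150.0)]
    stream, tl, cfg, norm = _simple_setup(72.0, events)
    wins = build_windows(stream, tl, cfg, norm, drop_untargeted=False)
    w0 = wins[0]  # [0, 24): must exclude the t=24 event
    assert w0.timestamps.tolist() == [1.0]
    w1 = wins[1]  # [8, 32): contains it
    assert 24.0 in w1.timestamps.tolist()


def test_short_stay_produces_no_windows():
    from coagcast.scoring import LabelEntry, LabelTimeline
    stream = LabEventStream("P1", [LabEvent(1.0, "PLT", 200.0, "")])
    tl = LabelTimeline("P1", 8.0, [LabelEntry(0, 0, 0, "observed"),
                                   LabelEntry(1, 0, 0, "observed")])
    cfg = EncodingConfig(variables=("PLT",), horizons_h=(8.0,))
    norm = Normalizer({"PLT": (50.0, 400.0)})
    assert build_windows(stream, tl, cfg, norm) == []


def test_empty_window_retained_with_zero_mask():
    events = [(1.0, "PLT", 200.0), (60.0, "PLT", 150.0)]
    stream, tl, cfg, norm = _simple_setup(72.0, events)
    wins = build_windows(stream, tl, cfg, norm, drop_untargeted=False)
    empty = [w for w in wins if w.n_obs == 0]
    assert empty, "windows without observations must be kept"
    w = empty[0]
    assert w.m.sum() == 0 and len(w.timestamps) == 1
    # interval continues from the full patient history
    assert w.delta_end[0] == pytest.approx(w.window_start_h + 24.0 - 1.0)


def test_delta_continues_across_window_boundaries():
    events = [(1.0, "PLT", 200.0), (30.0, "PLT", 180.0)]
    stream, tl, cfg, norm = _simple_setup(72.0, events)
    wins = build_windows(stream, tl, cfg, norm, drop_untargeted=False)
    w1 = wins[1]  # [8, 32) contains t=30; previous observation was t=1
    i = w1.timestamps.tolist().index(30.0)
    assert w1.delta[i, 0] == pytest.approx(29.0)


def test_mask_conservation_under_disjoint_tiling():
    cfg_cohort = CohortConfig(n_patients=5, max_stay_h=120.0, seed=9)
    streams, trajs = generate_cohort(cfg_cohort)
    tls = label_streams(streams, stays={t.patient_id: t.stay_h for t in trajs})
    enc = EncodingConfig(slide_step_h=24.0, horizons_h=(24.0,))
    norm = Normalizer.fit(streams, enc.variables)
    for s in streams:
        wins = build_windows(s, tls[s.patient_id], enc, norm, drop_untargeted=False)
        covered_end = max(w.window_start_h for w in wins) + 24.0
        expected = sum(1 for ev in s.events
                       if ev.variable in norm.stats and ev.time_h < covered_end - 1e-9)
        assert sum(w.m.sum() for w in wins) == expected


def test_encoding_of_one_patient_independent_of_other_test_patients(encoded_small):
    """No leakage: train-fitted statistics encode a test patient identically
    whether or not other test patients are present."""
    sc = encoded_small
    pid = sc.test_ids[0]
    alone = [w for w in sc.test if w.patient_id == pid]
    stream = next(s for s in sc.streams if s.patient_id == pid)
    solo = build_windows(stream, sc.timelines[pid], sc.enc, sc.normalizer)
    assert len(alone) == len(solo)
    for a, b in zip(alone, solo):
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.m, b.m)
        np.testing.assert_array_equal(a.delta, b.delta)


def test_discretized_vector_layout(toy_separable):
    cfg = EncodingConfig(variables=("V0", "V1"), horizons_h=(8.0,))
    vec = discretize_for_tabular(toy_separable[0], cfg)
    D = 2
    assert vec.shape == (3 * 2 * D + D,)
    names = tabular_feature_names(cfg, ("V0", "V1"))
    assert len(names) == vec.shape[0]


def test_discretized_last_values_match_single_observations():
    from coagcast.scoring import LabelEntry, LabelTimeline
    events = [(4.0, "PLT", 100.0), (12.0, "PLT", 200.0), (20.0, "PLT", 300.0)]
    stream, tl, cfg, norm = _simple_setup(32.0, events)
    w = build_windows(stream, tl, cfg, norm, drop_untargeted=False)[0]
    vec = discretize_for_tabular(w, cfg)
    names = tabular_feature_names(cfg, ("PLT", "INR"))
    lasts = [vec[names.index(f"cell{c}:PLT:last")] for c in range(3)]
    assert lasts == [norm.transform("PLT", v) for v in (100.0, 200.0, 300.0)]
    counts = [vec[names.index(f"cell{c}:PLT:count")] for c in range(3)]
    assert counts == [1, 1, 1]


def test_windows_jsonl_roundtrip(tmp_path, encoded_small):
    path = tmp_path / "w.jsonl"
    subset = encoded_small.test[:5]
    write_windows(subset, path, encoded_small.normalizer)
    back = read_windows(path)
    assert len(back) == len(subset)
    for a, b in zip(subset, back):
        np.testing.assert_allclose(a.x, b.x)
        np.testing.assert_allclose(a.delta, b.delta)
        assert a.targets == b.targets


@pytest.mark.parametrize("kwargs", [
    dict(sampling_window_h=24.0, slide_step_h=7.0),
    dict(horizons_h=(5.0,)),
    dict(discretization_grid_h=9.0),
])
def test_invalid_encoding_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        EncodingConfig(**kwargs)
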