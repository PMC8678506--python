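"""Irregular-stream encoding: mask/interval features, windows, discretization.

Turns a patient's irregular multivariate lab series X = {x_1, ..., x_T} with
timestamps s_t into model-ready tensors:

* mask      m_t^d = 1 iff variable d is observed at timestamp t;
* interval  delta_t^d = time since variable d was last observed, accumulated
  through unobserved steps (delta_1^d = 0; if m_{t-1}^d = 1 the interval
  restarts at s_t - s_{t-1}, otherwise the previous interval is carried and
  extended);
* step      Delta_t = s_t - s_{t-1}, the adjacent time step;

then slices the series into sliding sampling windows (default 24 h window,
8 h slide), attaches future disease labels at the configured horizons, and
offers a fixed-dimension discretized view for tabular models.

Values are min-max normalized with statistics learned on training patients
only (after clamping to configurable physiologic reportable ranges); missing
entries carry a fill value, recoverable through the mask — missingness is
modeled, never imputed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_PANEL, PHYSIOLOGIC_RANGES, LabEventStream
from .scoring import LabelTimeline

__all__ = [
    "EncodingConfig",
    "WindowTensor",
    "Normalizer",
    "compute_mask",
    "compute_intervals",
    "build_windows",
    "encode_cohort",
    "discretize_for_tabular",
    "tabular_feature_names",
    "windows_to_tabular",
    "window_targets",
    "write_windows",
    "read_windows",
]

DISEASES = ("SIC", "DIC")


@dataclass(frozen=True)
class EncodingConfig:
    """Windowing, horizon and normalization settings.

    Horizons are lead times measured from the *end* of the sampling window;
    the default ladder is 8n hours for n = 1..6.
    """

    sampling_window_h: float = 24.0
    slide_step_h: float = 8.0
    horizons_h: tuple = (8.0, 16.0, 24.0, 32.0, 40.0, 48.0)
    variables: tuple = DEFAULT_PANEL
    discretization_grid_h: float = 8.0
    fill_value: float = 0.0
    delta_scale_h: float = 48.0   # delta / delta_scale fed to sequence models

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizons_h", tuple(float(h) for h in self.horizons_h))
        object.__setattr__(self, "variables", tuple(self.variables))
        if self.slide_step_h <= 0 or self.sampling_window_h <= 0:
            raise ValueError("window and slide must be positive")
        if not math.isclose(self.sampling_window_h % self.slide_step_h, 0.0, abs_tol=1e-9):
            raise ValueError("slide_step_h must divide sampling_window_h evenly")
        for h in self.horizons_h:
            if h <= 0 or not math.isclose(h % self.slide_step_h, 0.0, abs_tol=1e-9):
                raise ValueError("horizons must be positive multiples of slide_step_h")
        rem = self.sampling_window_h % self.discretization_grid_h
        if not math.isclose(rem, 0.0, abs_tol=1e-9):
            raise ValueError("discretization grid must divide the sampling window")

    @property
    def n_grid_cells(self) -> int:
        return int(round(self.sampling_window_h / self.discretization_grid_h))


@dataclass
class WindowTensor:
    """Model input for one (patient, sampling-window) pair.

    ``timestamps`` are absolute in-stay hours (strictly increasing);
    ``x`` holds normalized values with ``fill`` where unobserved; ``m`` is the
    observation mask; ``steps`` are adjacent time steps Delta (first step is
    measured from the window start); ``delta`` is the per-variable interval
    feature continued across window boundaries using the full patient
    history.  ``targets`` maps horizon -> (sic_label, dic_label), either of
    which may be None when the future window had no label.
    """

    patient_id: str
    window_start_h: float
    window_len_h: float
    timestamps: np.ndarray     # [T]
    x: np.ndarray              # [T, D] normalized
    m: np.ndarray              # [T, D] in {0, 1}
    steps: np.ndarray          # [T] Delta
    delta: np.ndarray          # [T, D]
    targets: dict              # horizon_h -> (Optional[int], Optional[int])
    delta_end: np.ndarray = None  # [D] interval continued to window end

    @property
    def n_obs(self) -> int:
        return int(self.m.sum())

    def target(self, disease: str, horizon_h: float):
        pair = self.targets.get(horizon_h)
        if pair is None:
            return None
        return pair[0] if disease == "SIC" else pair[1]


class Normalizer:
    """Per-variable min-max normalization learned from training patients only.

    Raw values are clamped to physiologic reportable ranges before the
    min/max are taken; at transform time values are scaled and clamped to
    [0, 1], so a test value above the training maximum maps to 1.  Variables
    that are constant on the training data are flagged and dropped with a
    warning.
    """

    def __init__(self, stats: Mapping[str, tuple], dropped: Sequence[str] = ()):
        self.stats = dict(stats)
        self.dropped = tuple(dropped)

    @classmethod
    def fit(cls, streams: Iterable[LabEventStream], variables: Sequence[str],
            ranges: Mapping[str, tuple] = PHYSIOLOGIC_RANGES) -> "Normalizer":
        pools: dict = {v: [] for v in variables}
        for s in streams:
            for ev in s.events:
                if ev.variable in pools:
                    lo, hi = ranges.get(ev.variable, (-np.inf, np.inf))
                    pools[ev.variable].append(float(np.clip(ev.value, lo, hi)))
        stats, dropped = {}, []
        for v in variables:
            vals = pools[v]
            if not vals:
                dropped.append(v)
                continue
            lo, hi = min(vals), max(vals)
            if hi <= lo:
                dropped.append(v)
                continue
            stats[v] = (lo, hi)
        if dropped:
            warnings.warn(
                f"variables constant or unobserved on training data, dropped: {dropped}"
            )
        return cls(stats, dropped)

    def transform(self, variable: str, values):
        lo, hi = self.stats[variable]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def kept(self, variables: Sequence[str]) -> tuple:
        return tuple(v for v in variables if v in self.stats)

    def to_json(self) -> str:
        return json.dumps({"stats": self.stats, "dropped": list(self.dropped)},
                          sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Normalizer":
        obj = json.loads(text)
        return cls({k: tuple(v) for k, v in obj["stats"].items()}, obj["dropped"])


def compute_mask(values: np.ndarray) -> np.ndarray:
    """Observation mask: 1 where a value is present (non-NaN), else 0."""
    return (~np.isnan(np.asarray(values, dtype=float))).astype(float)


def compute_intervals(timestamps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Interval feature delta_t^d from timestamps and the observation mask.

    delta_1^d = 0; for t > 1, delta_t^d = s_t - s_{t-1} when variable d was
    observed at t-1, and s_t - s_{t-1} + delta_{t-1}^d when it was not (the
    gap accumulates through unobserved steps).
    """
    s = np.asarray(timestamps, dtype=float)
    m = np.asarray(mask, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    T, D = m.shape
    if s.shape[0] != T:
        raise ValueError("timestamps and mask length mismatch")
    if np.any(np.diff(s) < 0):
        raise ValueError("timestamps must be sorted ascending")
    delta = np.zeros((T, D))
    for t in range(1, T):
        gap = s[t] - s[t - 1]
        delta[t] = gap + np.where(m[t - 1] == 0, delta[t - 1], 0.0)
    return delta


def _stream_grid(stream: LabEventStream, variables: Sequence[str]):
    """Unique-timestamp grid: (times [T], raw values [T, D] with NaN, mask)."""
    var_index = {v: j for j, v in enumerate(variables)}
    times = sorted({ev.time_h for ev in stream.events if ev.variable in var_index})
    t_index = {t: i for i, t in enumerate(times)}
    raw = np.full((len(times), len(variables)), np.nan)
    for ev in stream.events:
        j = var_index.get(ev.variable)
        if j is not None:
            raw[t_index[ev.time_h], j] = ev.value
    return np.asarray(times, dtype=float), raw


def build_windows(stream: LabEventStream, timeline: LabelTimeline,
                  config: EncodingConfig, normalizer: Normalizer,
                  drop_untargeted: bool = True) -> list:
    """Slice one patient's stream into sliding-window tensors with targets.

    Window membership is half-open [start, start + window).  One window is
    produced per slide position whose sampling window lies fully in-stay;
    the target at horizon h is the timeline label of the window containing
    window_end + h.  Windows whose targets are absent at every horizon are
    dropped; windows with zero observations are retained (their missingness
    is itself signal) as a single all-masked pseudo-observation at the window
    end.
    """
    variables = normalizer.kept(config.variables)
    D = len(variables)
    times, raw = _stream_grid(stream, variables)
    mask_full = compute_mask(raw)
    if times.size:
        delta_full = compute_intervals(times, mask_full)
    else:
        delta_full = np.zeros((0, D))
    x_full = np.full_like(raw, config.fill_value)
    for j, v in enumerate(variables):
        obs = mask_full[:, j] == 1
        if obs.any():
            x_full[obs, j] = normalizer.transform(v, raw[obs, j])

    def delta_at(t: float) -> np.ndarray:
        """Eq.-style continuation of the interval feature to time t."""
        out = np.empty(D)
        for j in range(D):
            obs_times = times[mask_full[:, j] == 1]
            prior = obs_times[obs_times < t]
            if prior.size:
                out[j] = t - prior[-1]
            elif times.size and times[0] < t:
                out[j] = t - times[0]
            else:
                out[j] = 0.0
        return out

    total_h = timeline.total_h
    W = config.sampling_window_h
    out = []
    start = 0.0
    while start + W <= total_h + 1e-9:
        end = start + W
        sel = (times >= start - 1e-9) & (times < end - 1e-9)
        idx = np.nonzero(sel)[0]
        if idx.size:
            ts = times[idx]
            x, m, dlt = x_full[idx], mask_full[idx], delta_full[idx]
            steps = np.diff(np.concatenate([[start], ts]))
        else:
            ts = np.array([end])
            x = np.full((1, D), config.fill_value)
            m = np.zeros((1, D))
            dlt = delta_at(end)[None, :]
            steps = np.array([W])
        targets = {}
        any_target = False
        for h in config.horizons_h:
            t_target = end + h
            sic = timeline.label_at(t_target, "SIC")
            dic = timeline.label_at(t_target, "DIC")
            if t_target >= total_h:
                sic = dic = None
            targets[h] = (sic, dic)
            any_target = any_target or sic is not None or dic is not None
        if any_target or not drop_untargeted:
            out.append(WindowTensor(
                patient_id=stream.patient_id, window_start_h=start, window_len_h=W,
                timestamps=ts, x=x, m=m, steps=steps, delta=dlt, targets=targets,
                delta_end=delta_at(end),
            ))
        start += config.slide_step_h
    return out


def encode_cohort(streams, timelines: Mapping[str, LabelTimeline],
                  config: EncodingConfig, normalizer: Normalizer) -> list:
    """Encode every patient; returns a flat list of WindowTensors."""
    windows = []
    for s in streams:
        tl = timelines.get(s.patient_id)
        if tl is None:
            continue
        windows.extend(build_windows(s, tl, config, normalizer))
    return windows


# ---------------------------------------------------------------------------
# Discretized fixed-dimension view for tabular models

def tabular_feature_names(config: EncodingConfig, variables: Sequence[str]) -> list:
    names = []
    for c in range(config.n_grid_cells):
        for v in variables:
            names.append(f"cell{c}:{v}:last")
            names.append(f"cell{c}:{v}:count")
    names.extend(f"{v}:delta_end" for v in variables)
    return names


def discretize_for_tabular(window: WindowTensor, config: EncodingConfig) -> np.ndarray:
    """Fixed-length vector: per grid cell and variable the last observed
    value (or fill) and the observation count, concatenated with the
    per-variable interval continued to the window end (scaled)."""
    C = config.n_grid_cells
    D = window.x.shape[1]
    grid = config.discretization_grid_h
    feats = np.empty(C * 2 * D)
    rel = window.timestamps - window.window_start_h
    k = 0
    for c in range(C):
        lo, hi = c * grid, (c + 1) * grid
        in_cell = (rel >= lo - 1e-9) & (rel < hi - 1e-9)
        for d in range(D):
            rows = np.nonzero(in_cell & (window.m[:, d] == 1))[0]
            feats[k] = window.x[rows[-1], d] if rows.size else config.fill_value
            feats[k + 1] = rows.size
            k += 2
    return np.concatenate([feats, window.delta_end / config.delta_scale_h])


def windows_to_tabular(windows: Sequence[WindowTensor], config: EncodingConfig,
                       variables: Sequence[str]):
    """(X matrix [N, F], meta frame with patient_id / window_start_h)."""
    X = np.stack([discretize_for_tabular(w, config) for w in windows]) if windows \
        else np.zeros((0, len(tabular_feature_names(config, variables))))
    meta = pd.DataFrame({
        "patient_id": [w.patient_id for w in windows],
        "window_start_h": [w.window_start_h for w in windows],
    })
    return X, meta


def window_targets(windows: Sequence[WindowTensor], disease: str, horizon_h: float):
    """(y [N] with -1 for absent, valid mask [N]) for one disease/horizon."""
    y = np.array([
        -1 if (lab := w.target(disease, horizon_h)) is None else lab
        for w in windows
    ])
    return y, y >= 0


# ---------------------------------------------------------------------------
# JSON-lines export of encoded datasets

def write_windows(windows: Sequence[WindowTensor], path,
                  normalizer: Optional[Normalizer] = None) -> None:
    with open(path, "w") as fh:
        for w in windows:
            rec = {
                "patient_id": w.patient_id,
                "window_start_h": w.window_start_h,
                "window_len_h": w.window_len_h,
                "timestamps": w.timestamps.tolist(),
                "x": w.x.tolist(),
                "m": w.m.tolist(),
                "steps": w.steps.tolist(),
                "delta": w.delta.tolist(),
                "delta_end": w.delta_end.tolist(),
                "targets": {str(h): list(v) for h, v in w.targets.items()},
            }
            fh.write(json.dumps(rec) + "\n")
    if normalizer is not None:
        with open(str(path) + ".norm.json", "w") as fh:
            fh.write(normalizer.to_json())


def read_windows(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(WindowTensor(
                patient_id=rec["patient_id"],
                window_start_h=rec["window_start_h"],
                window_len_h=rec["window_len_h"],
                timestamps=np.asarray(rec["timestamps"], dtype=float),
                x=np.asarray(rec["x"], dtype=float),
                m=np.asarray(rec["m"], dtype=float),
                steps=np.asarray(rec["steps"], dtype=float),
                delta=np.asarray(rec["delta"], dtype=float),
                delta_end=np.asarray(rec["delta_end"], dtype=float),
                targets={float(h): tuple(None if x is None else int(x) for x in v)
                         for h, v in rec["targets"].items()},
            ))
    return out
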