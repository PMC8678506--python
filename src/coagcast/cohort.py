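"""Synthetic sepsis cohort generator with known SIC/DIC progression.

Real cohorts behind early-warning coagulopathy models are private hospital
extracts.  This module generates irregular, informatively-missing laboratory
event streams whose ground truth (latent disease state over time) is known
exactly, so that every downstream stage — scoring, labeling, encoding,
modeling, evaluation, interpretation — can be tested end to end without any
data download.

The generative model is openly synthetic and deliberately simple:

* each patient follows a monotone latent path
  healthy-sepsis -> SIC -> overt DIC (no reversal), with onset times drawn
  per patient;
* each laboratory variable has a state-conditional mean; means drift
  piecewise-linearly toward the next state over a lead window before onset
  and settle shortly after, with lognormal multiplicative noise;
* observations arrive via a thinned-Poisson *blood draw* process whose
  intensity increases with latent severity (sicker patients are sampled more
  often — the informative-missingness mechanism), each draw containing a
  random subset of the panel;
* SOFA is emitted as an already-computed daily score stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PANEL",
    "STATE_MEANS",
    "PHYSIOLOGIC_RANGES",
    "UNITS",
    "CohortConfig",
    "CohortFormatError",
    "LabEvent",
    "LabEventStream",
    "LatentTrajectory",
    "generate_cohort",
    "read_cohort",
    "read_truth",
    "streams_to_frame",
    "frame_to_streams",
    "write_cohort",
    "write_truth",
]

#: Default laboratory panel: the coagulation-centric variables that dominate
#: feature importance in sepsis coagulopathy prediction, plus SOFA and lactate.
DEFAULT_PANEL = (
    "PLT", "INR", "PT", "APTT", "D-dimer", "FDP", "FIB", "SOFA", "PCT", "lactate",
)

#: Units written to cohort files.  PCT is plateletcrit (%), not procalcitonin.
UNITS = {
    "PLT": "1e9/L",
    "INR": "ratio",
    "PT": "s",
    "APTT": "s",
    "D-dimer": "mg/L FEU",
    "FDP": "mg/L",
    "FIB": "g/L",
    "SOFA": "score",
    "PCT": "%",
    "lactate": "mmol/L",
}

#: State-conditional trajectory means: (healthy-sepsis, SIC, overt DIC).
#: Chosen so that applying the SIC / ISTH overt-DIC scores to the noiseless
#: means recovers the latent state decisively (platelets and fibrinogen fall,
#: INR/PT/fibrin markers rise along the progression).
STATE_MEANS = {
    "PLT": (220.0, 95.0, 40.0),
    "INR": (1.05, 1.50, 1.90),
    "PT": (12.5, 15.5, 19.5),
    "APTT": (32.0, 42.0, 55.0),
    "D-dimer": (0.6, 2.5, 7.0),
    "FDP": (4.0, 12.0, 30.0),
    "FIB": (3.5, 2.2, 0.8),
    "SOFA": (2.0, 5.0, 8.0),
    "PCT": (0.22, 0.12, 0.05),
    "lactate": (1.5, 3.0, 5.0),
}

#: Configurable physiologic reportable ranges used for clamping raw values
#: before normalization (stand-ins for laboratory reportable ranges).
PHYSIOLOGIC_RANGES = {
    "PLT": (1.0, 1000.0),
    "INR": (0.5, 10.0),
    "PT": (8.0, 60.0),
    "APTT": (15.0, 150.0),
    "D-dimer": (0.01, 50.0),
    "FDP": (0.5, 150.0),
    "FIB": (0.2, 10.0),
    "SOFA": (0.0, 24.0),
    "PCT": (0.01, 1.0),
    "lactate": (0.3, 20.0),
}


class CohortFormatError(ValueError):
    """Raised for malformed cohort files; messages name the offending row."""


class LabEvent(NamedTuple):
    time_h: float
    variable: str
    value: float
    unit: str


@dataclass
class LabEventStream:
    """One patient's irregular, timestamped multivariate lab observations."""

    patient_id: str
    events: list  # list[LabEvent], sorted by (time_h, variable)

    def validate(self) -> None:
        last_t = -1.0
        seen = set()
        for i, ev in enumerate(self.events):
            if ev.time_h < 0:
                raise CohortFormatError(
                    f"patient {self.patient_id}, event {i}: negative time_h {ev.time_h}"
                )
            if ev.time_h < last_t:
                raise CohortFormatError(
                    f"patient {self.patient_id}, event {i}: times not sorted"
                )
            key = (ev.time_h, ev.variable)
            if key in seen:
                raise CohortFormatError(
                    f"patient {self.patient_id}, event {i}: duplicate (time_h, variable) {key}"
                )
            seen.add(key)
            last_t = ev.time_h

    @property
    def variables(self) -> set:
        return {ev.variable for ev in self.events}

    def last_time(self) -> float:
        return self.events[-1].time_h if self.events else 0.0


@dataclass
class LatentTrajectory:
    """Ground-truth latent disease path for one synthetic patient.

    States are monotone non-decreasing in severity: 0 = healthy-sepsis,
    1 = SIC, 2 = overt DIC.  ``dic_onset_h`` present implies ``sic_onset_h``
    present and not later.
    """

    patient_id: str
    stay_h: float
    sic_onset_h: Optional[float] = None
    dic_onset_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dic_onset_h is not None:
            if self.sic_onset_h is None:
                raise ValueError("dic_onset_h requires sic_onset_h")
            if self.dic_onset_h < self.sic_onset_h:
                raise ValueError("dic_onset_h must be >= sic_onset_h")

    def state_at(self, t: float) -> int:
        if self.dic_onset_h is not None and t >= self.dic_onset_h:
            return 2
        if self.sic_onset_h is not None and t >= self.sic_onset_h:
            return 1
        return 0

    @property
    def ever_sic(self) -> bool:
        return self.sic_onset_h is not None

    @property
    def ever_dic(self) -> bool:
        return self.dic_onset_h is not None


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Prevalence targets default to the annotated sepsis cohort this package
    emulates (SIC 37.1%, overt DIC 17.8%); progression is strictly
    sequential, so the DIC target may not exceed the SIC target.
    """

    n_patients: int
    max_stay_h: float = 240.0
    min_stay_h: float = 96.0
    target_sic_prevalence: float = 0.371
    target_dic_prevalence: float = 0.178
    sampling_rate_base: float = 3.0       # expected obs per variable per 24 h
    severity_sampling_coupling: float = 0.5
    noise_scale: float = 0.08             # lognormal sigma on positive variables
    seed: int = 0
    panel: tuple = DEFAULT_PANEL
    draw_inclusion_prob: float = 0.7      # P(variable included | blood draw)
    onset_lead_h: float = 16.0            # pre-onset drift window
    onset_settle_h: float = 4.0           # post-onset settling window
    lead_fraction: float = 0.45           # drift covers this fraction pre-onset
    signal_variables: Optional[tuple] = None  # None = all state-dependent

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not (0.0 < self.target_sic_prevalence < 1.0):
            raise ValueError("target_sic_prevalence must be in (0, 1)")
        if not (0.0 < self.target_dic_prevalence < 1.0):
            raise ValueError("target_dic_prevalence must be in (0, 1)")
        if self.target_dic_prevalence > self.target_sic_prevalence:
            raise ValueError(
                "target_dic_prevalence cannot exceed target_sic_prevalence "
                "(progression is sequential)"
            )
        if self.sampling_rate_base <= 0:
            raise ValueError("sampling_rate_base must be positive")
        if self.severity_sampling_coupling < 0:
            raise ValueError("severity_sampling_coupling must be nonnegative")
        if self.min_stay_h < 64.0 or self.max_stay_h < self.min_stay_h:
            raise ValueError("require max_stay_h >= min_stay_h >= 64")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        unknown = set(self.panel) - set(STATE_MEANS)
        if unknown:
            raise ValueError(f"panel variables without trajectory model: {sorted(unknown)}")


def _ramp_weight(t: float, onset: float, lead: float, settle: float, frac: float) -> float:
    """Drift weight toward the next state: 0 before the lead window, rising
    to ``frac`` at onset, then to 1 over the settling window."""
    if t < onset - lead:
        return 0.0
    if t < onset:
        return frac * (t - (onset - lead)) / lead
    if t < onset + settle:
        return frac + (1.0 - frac) * (t - onset) / settle
    return 1.0


def _trajectory_mean(var: str, t: float, traj: LatentTrajectory, cfg: CohortConfig) -> float:
    healthy, sic, dic = STATE_MEANS[var]
    if cfg.signal_variables is not None and var not in cfg.signal_variables:
        return healthy
    m = healthy
    if traj.sic_onset_h is not None:
        ws = _ramp_weight(t, traj.sic_onset_h, cfg.onset_lead_h, cfg.onset_settle_h,
                          cfg.lead_fraction)
        m = healthy + ws * (sic - healthy)
    if traj.dic_onset_h is not None:
        wd = _ramp_weight(t, traj.dic_onset_h, cfg.onset_lead_h, cfg.onset_settle_h,
                          cfg.lead_fraction)
        m = m + wd * (dic - m)
    return m


def _sample_patient(index: int, cfg: CohortConfig):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, index]))
    pid = f"P{index:05d}"
    stay = rng.uniform(cfg.min_stay_h, cfg.max_stay_h)

    u = rng.uniform()
    sic_onset = dic_onset = None
    if u < cfg.target_sic_prevalence:
        sic_onset = rng.uniform(24.0, stay - 40.0)
        if u < cfg.target_dic_prevalence:
            gap_hi = min(72.0, stay - sic_onset - 8.0)
            dic_onset = sic_onset + rng.uniform(16.0, gap_hi)
    traj = LatentTrajectory(pid, stay_h=stay, sic_onset_h=sic_onset, dic_onset_h=dic_onset)

    def severity(t: float) -> int:
        return traj.state_at(t)

    # Blood-draw point process: thinned Poisson, intensity coupled to severity.
    vars_lab = [v for v in cfg.panel if v != "SOFA"]
    draw_rate = cfg.sampling_rate_base / max(cfg.draw_inclusion_prob, 1e-9)
    lam_max = draw_rate / 24.0 * (1.0 + 2.0 * cfg.severity_sampling_coupling)
    n_cand = rng.poisson(lam_max * stay)
    cand = np.sort(rng.uniform(0.0, stay, size=n_cand))
    keep = rng.uniform(size=n_cand) < (
        (draw_rate / 24.0)
        * (1.0 + cfg.severity_sampling_coupling * np.array([severity(t) for t in cand]))
        / lam_max
    )
    draw_times = cand[keep]

    events = {}

    def emit(t: float, var: str) -> None:
        t = round(float(t), 2)
        key = (t, var)
        if key in events:
            return
        mean = _trajectory_mean(var, t, traj, cfg)
        if var == "SOFA":
            val = float(np.clip(round(mean + rng.normal(0.0, 0.6)), 0, 24))
        else:
            val = mean * math.exp(rng.normal(0.0, cfg.noise_scale))
            lo, hi = PHYSIOLOGIC_RANGES[var]
            val = float(np.clip(round(val, 4), lo, hi))
        events[key] = LabEvent(t, var, val, UNITS[var])

    # Admission panel: guarantees labs within the first 24 h.
    for var in cfg.panel:
        emit(1.0, var)
    # Daily SOFA.
    t = 25.0
    while t <= stay:
        emit(t, "SOFA")
        t += 24.0
    # Irregular draws, each with a random subset of the lab panel.
    for t in draw_times:
        included = [v for v in vars_lab if rng.uniform() < cfg.draw_inclusion_prob]
        for var in included:
            emit(t, var)

    ordered = sorted(events.values(), key=lambda ev: (ev.time_h, ev.variable))
    stream = LabEventStream(pid, ordered)
    stream.validate()
    return stream, traj


def generate_cohort(config: CohortConfig):
    """Generate a cohort of event streams plus their ground-truth trajectories.

    Deterministic given ``config.seed``; each patient's substream is derived
    from ``(seed, patient index)`` so cohorts are stable under changes of
    ``n_patients``.

    Returns
    -------
    (streams, trajectories) : (list[LabEventStream], list[LatentTrajectory])
    """
    streams, trajs = [], []
    for i in range(config.n_patients):
        s, tr = _sample_patient(i, config)
        streams.append(s)
        trajs.append(tr)
    return streams, trajs


# ---------------------------------------------------------------------------
# Cohort file I/O: delimited text, columns patient_id,time_h,variable,value,unit

_COLUMNS = ["patient_id", "time_h", "variable", "value", "unit"]


def streams_to_frame(streams: Iterable[LabEventStream]) -> pd.DataFrame:
    rows = [
        (s.patient_id, ev.time_h, ev.variable, ev.value, ev.unit)
        for s in streams
        for ev in s.events
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_streams(frame: pd.DataFrame) -> list:
    streams = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        events = [
            LabEvent(float(r.time_h), str(r.variable), float(r.value), str(r.unit))
            for r in grp.itertuples()
        ]
        events.sort(key=lambda ev: (ev.time_h, ev.variable))
        stream = LabEventStream(str(pid), events)
        stream.validate()
        streams.append(stream)
    return streams


def write_cohort(streams: Iterable[LabEventStream], path) -> None:
    streams_to_frame(streams).to_csv(path, index=False)


def read_cohort(path) -> list:
    """Read a cohort CSV, validating each row; errors name the file row."""
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str, "variable": str, "unit": str})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortFormatError(f"unparseable cohort file {path}: {exc}") from exc
    missing = set(_COLUMNS) - set(frame.columns)
    if missing:
        raise CohortFormatError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(frame.itertuples(), start=2):  # header is line 1
        t = row.time_h
        v = row.value
        if pd.isna(t) or not np.isfinite(t):
            raise CohortFormatError(f"{path}, line {i}: non-numeric time_h {t!r}")
        if t < 0:
            raise CohortFormatError(f"{path}, line {i}: negative time_h {t}")
        if pd.isna(v) or not np.isfinite(v):
            raise CohortFormatError(f"{path}, line {i}: non-numeric value {v!r}")
    return frame_to_streams(frame)


def write_truth(trajectories: Iterable[LatentTrajectory], path) -> None:
    """Ground-truth sidecar (consumed only by tests and the evaluation of
    recovery experiments): onset hours are empty when absent."""
    rows = [
        (tr.patient_id, tr.sic_onset_h, tr.dic_onset_h, tr.stay_h)
        for tr in trajectories
    ]
    pd.DataFrame(rows, columns=["patient_id", "sic_onset_h", "dic_onset_h", "stay_h"]).to_csv(
        path, index=False
    )


def read_truth(path) -> list:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for row in frame.itertuples():
        sic = None if pd.isna(row.sic_onset_h) else float(row.sic_onset_h)
        dic = None if pd.isna(row.dic_onset_h) else float(row.dic_onset_h)
        out.append(LatentTrajectory(str(row.patient_id), float(row.stay_h), sic, dic))
    return out
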