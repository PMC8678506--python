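"""SIC and ISTH overt-DIC scoring, sequential diagnosis, and window labels.

Implements the ground-truth annotation stage: compute the sepsis-induced
coagulopathy (SIC) score (platelets, PT-INR, SOFA) and the ISTH overt-DIC
score (platelets, fibrin marker, PT prolongation, fibrinogen) at every
timestamp where a scoring variable updates, apply the two-step sequential
diagnosis (overt DIC is labeled only on the SIC -> DIC progression path),
and collapse assessments into 8 h window labels with forward interpolation
for windows that received no qualifying laboratory data.

Default bin thresholds follow the published SIC (Iba 2017) and ISTH overt-DIC
(2001) tables; every threshold is configurable and the configuration should
be echoed alongside outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoringCutoffs",
    "SicResult",
    "DicResult",
    "CoagAssessment",
    "LabelEntry",
    "LabelTimeline",
    "sic_score",
    "isth_dic_score",
    "assess_stream",
    "build_label_timeline",
    "label_streams",
    "write_timelines",
    "read_timelines",
]


@dataclass(frozen=True)
class ScoringCutoffs:
    """Thresholds for the SIC and ISTH overt-DIC scoring systems.

    Platelet cut pairs are (mild, severe) in descending order; all other cut
    pairs ascend.  ``dic_fibrin_marker`` names the preferred fibrin-related
    marker (D-dimer, mg/L FEU); when it is missing at assessment time, FDP is
    used as fallback with ``dic_fdp_fallback_cuts``.
    """

    sic_plt_cuts: tuple = (150.0, 100.0)       # x10^9/L, score 1 / 2
    sic_inr_cuts: tuple = (1.2, 1.4)           # score 1 / 2 (strictly above)
    sic_sofa_cuts: tuple = (1, 2)              # score 1 / 2 (at or above)
    sic_positive_total: int = 4                # SIC total in [0, 6]
    sic_require_coag_subscore: bool = False    # variant: platelet+INR subscores > 2
    dic_plt_cuts: tuple = (100.0, 50.0)        # score 1 / 2
    dic_fibrin_marker: str = "D-dimer"
    dic_fibrin_cuts: tuple = (1.0, 5.0)        # mg/L FEU: moderate / strong increase
    dic_fdp_fallback_cuts: tuple = (10.0, 25.0)  # mg/L
    dic_pt_prolong_cuts: tuple = (3.0, 6.0)    # seconds prolonged: score 1 / 2
    dic_pt_reference_s: float = 12.0           # laboratory PT reference
    dic_fib_cut: float = 1.0                   # g/L, score 1 below
    dic_positive_total: int = 5                # DIC total in [0, 8]
    sequential: bool = True                    # two-step SIC -> overt-DIC diagnosis

    def __post_init__(self) -> None:
        for name, cuts, descending in [
            ("sic_plt_cuts", self.sic_plt_cuts, True),
            ("sic_inr_cuts", self.sic_inr_cuts, False),
            ("sic_sofa_cuts", self.sic_sofa_cuts, False),
            ("dic_plt_cuts", self.dic_plt_cuts, True),
            ("dic_fibrin_cuts", self.dic_fibrin_cuts, False),
            ("dic_fdp_fallback_cuts", self.dic_fdp_fallback_cuts, False),
            ("dic_pt_prolong_cuts", self.dic_pt_prolong_cuts, False),
        ]:
            a, b = cuts
            if (a <= b) if descending else (a >= b):
                raise ValueError(f"{name} must be strictly ordered: {cuts}")
        if not (0 <= self.sic_positive_total <= 6):
            raise ValueError("sic_positive_total outside achievable range [0, 6]")
        if not (0 <= self.dic_positive_total <= 8):
            raise ValueError("dic_positive_total outside achievable range [0, 8]")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


class SicResult(NamedTuple):
    subscores: tuple  # (plt, inr, sofa)
    total: int
    positive: bool


class DicResult(NamedTuple):
    subscores: tuple  # (plt, fibrin_marker, pt, fib)
    total: int
    positive: bool    # raw positivity (before the sequential condition)


def sic_score(plt: float, inr: float, sofa: float,
              cutoffs: ScoringCutoffs = ScoringCutoffs()) -> SicResult:
    """SIC score: each subscore in {0, 1, 2}, positive at the total threshold.

    Platelets score 1 below the mild cut and 2 below the severe cut; INR
    scores strictly above its cuts; SOFA scores at or above its cuts.
    """
    if plt <= 0 or inr <= 0:
        raise ValueError("plt and inr must be positive")
    if sofa < 0:
        raise ValueError("sofa must be nonnegative")
    mild, severe = cutoffs.sic_plt_cuts
    plt_sub = 2 if plt < severe else (1 if plt < mild else 0)
    lo, hi = cutoffs.sic_inr_cuts
    inr_sub = 2 if inr > hi else (1 if inr > lo else 0)
    lo, hi = cutoffs.sic_sofa_cuts
    sofa_sub = 2 if sofa >= hi else (1 if sofa >= lo else 0)
    total = plt_sub + inr_sub + sofa_sub
    positive = total >= cutoffs.sic_positive_total
    if cutoffs.sic_require_coag_subscore:
        positive = positive and (plt_sub + inr_sub > 2)
    return SicResult((plt_sub, inr_sub, sofa_sub), total, positive)


def isth_dic_score(plt: float, fibrin_marker_value: float, pt_seconds: float,
                   fibrinogen_gL: float, cutoffs: ScoringCutoffs = ScoringCutoffs(),
                   marker_cuts: Optional[tuple] = None) -> DicResult:
    """ISTH overt-DIC score: platelet bin {0,1,2}, fibrin-marker bin {0,2,3},
    PT-prolongation bin {0,1,2}, fibrinogen bin {0,1}; positive at total >= 5.

    PT prolongation is ``pt_seconds - dic_pt_reference_s``.  ``marker_cuts``
    overrides the fibrin-marker thresholds (used for the FDP fallback).
    """
    if min(plt, fibrin_marker_value, pt_seconds, fibrinogen_gL) <= 0:
        raise ValueError("all inputs must be positive")
    mild, severe = cutoffs.dic_plt_cuts
    plt_sub = 2 if plt < severe else (1 if plt < mild else 0)
    lo, hi = marker_cuts if marker_cuts is not None else cutoffs.dic_fibrin_cuts
    marker_sub = 3 if fibrin_marker_value > hi else (2 if fibrin_marker_value >= lo else 0)
    prolong = pt_seconds - cutoffs.dic_pt_reference_s
    lo, hi = cutoffs.dic_pt_prolong_cuts
    pt_sub = 2 if prolong > hi else (1 if prolong >= lo else 0)
    fib_sub = 1 if fibrinogen_gL < cutoffs.dic_fib_cut else 0
    total = plt_sub + marker_sub + pt_sub + fib_sub
    return DicResult((plt_sub, marker_sub, pt_sub, fib_sub), total,
                     total >= cutoffs.dic_positive_total)


@dataclass
class CoagAssessment:
    """SIC and ISTH overt-DIC assessment at one timestamp.

    ``sic_positive`` / ``dic_positive`` are None when the respective score was
    not computable (a required input missing or stale); missing inputs are
    never imputed.  ``dic_positive`` includes the sequential condition;
    ``dic_positive_raw`` is score positivity alone.
    """

    time_h: float
    sic_subscores: Optional[tuple] = None
    sic_total: Optional[int] = None
    sic_positive: Optional[bool] = None
    dic_subscores: Optional[tuple] = None
    dic_total: Optional[int] = None
    dic_positive_raw: Optional[bool] = None
    dic_positive: Optional[bool] = None
    inputs_used: dict = field(default_factory=dict)  # variable -> (value, source time_h)


_SIC_VARS = ("PLT", "INR", "SOFA")


def assess_stream(stream, cutoffs: ScoringCutoffs = ScoringCutoffs(),
                  staleness_h: float = 24.0) -> list:
    """Score a lab stream at every timestamp where a scoring variable updates.

    Each score input takes the variable's most recent observation within
    ``staleness_h`` hours (last observation carried forward with a staleness
    horizon); a score with any required input missing or stale is marked not
    computable.  The sequential condition makes an assessment DIC-positive
    only if SIC positivity has been reached at or before the same timestamp.
    """
    relevant = {"PLT", "INR", "SOFA", "PT", "FIB", cutoffs.dic_fibrin_marker, "FDP"}
    last: dict = {}
    by_time: dict = {}
    for ev in stream.events:
        if ev.variable in relevant:
            by_time.setdefault(ev.time_h, []).append(ev)

    out: list = []
    sic_seen = False
    for t in sorted(by_time):
        for ev in by_time[t]:
            last[ev.variable] = (ev.value, ev.time_h)

        def fresh(var: str):
            if var in last and t - last[var][1] <= staleness_h:
                return last[var]
            return None

        a = CoagAssessment(time_h=t)
        sic_in = {v: fresh(v) for v in _SIC_VARS}
        if all(sic_in.values()):
            res = sic_score(sic_in["PLT"][0], sic_in["INR"][0], sic_in["SOFA"][0], cutoffs)
            a.sic_subscores, a.sic_total, a.sic_positive = res
            a.inputs_used.update(sic_in)
            if res.positive:
                sic_seen = True

        marker = fresh(cutoffs.dic_fibrin_marker)
        marker_cuts = None
        marker_name = cutoffs.dic_fibrin_marker
        if marker is None:
            marker = fresh("FDP")
            marker_cuts = cutoffs.dic_fdp_fallback_cuts
            marker_name = "FDP"
        dic_in = {"PLT": fresh("PLT"), "PT": fresh("PT"), "FIB": fresh("FIB")}
        if marker is not None and all(dic_in.values()):
            res = isth_dic_score(dic_in["PLT"][0], marker[0], dic_in["PT"][0],
                                 dic_in["FIB"][0], cutoffs, marker_cuts=marker_cuts)
            a.dic_subscores, a.dic_total, a.dic_positive_raw = res
            a.dic_positive = bool(res.positive and (sic_seen or not cutoffs.sequential))
            a.inputs_used.update(dic_in)
            a.inputs_used[marker_name] = marker
        out.append(a)
    return out


class LabelEntry(NamedTuple):
    window_index: int
    sic_label: Optional[int]   # 0/1, or None when absent
    dic_label: Optional[int]
    provenance: str            # "observed" | "interpolated" | "absent"


@dataclass
class LabelTimeline:
    """Per-window SIC/DIC labels for one patient with provenance."""

    patient_id: str
    window_len_h: float
    labels: list  # list[LabelEntry], window_index contiguous from 0

    @property
    def n_windows(self) -> int:
        return len(self.labels)

    @property
    def total_h(self) -> float:
        return self.n_windows * self.window_len_h

    def label_at(self, time_h: float, disease: str) -> Optional[int]:
        """Label of the window containing ``time_h`` (half-open windows)."""
        idx = int(time_h // self.window_len_h)
        if not (0 <= idx < self.n_windows):
            return None
        entry = self.labels[idx]
        return entry.sic_label if disease == "SIC" else entry.dic_label

    def onset_window(self, disease: str) -> Optional[int]:
        """First window labeled positive, or None."""
        for entry in self.labels:
            lab = entry.sic_label if disease == "SIC" else entry.dic_label
            if lab == 1:
                return entry.window_index
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.patient_id, e.window_index, e.window_index * self.window_len_h,
             e.sic_label, e.dic_label, e.provenance)
            for e in self.labels
        ]
        return pd.DataFrame(rows, columns=[
            "patient_id", "window_index", "window_start_h",
            "sic_label", "dic_label", "provenance",
        ])


def _interpolate_channel(observed: list) -> list:
    """Fill absent labels between/after observed ones.

    Between two observed labels: if the flanking labels agree, the gap takes
    that label; if they disagree, the earlier label wins (forward fill —
    past-to-future, avoiding look-ahead leakage).  Trailing windows after the
    last observation are forward-filled; leading windows stay absent.
    """
    n = len(observed)
    filled = list(observed)
    obs_idx = [i for i, v in enumerate(observed) if v is not None]
    if not obs_idx:
        return filled
    for a, b in zip(obs_idx[:-1], obs_idx[1:]):
        # agreement takes the shared label; disagreement resolves forward —
        # either way the earlier observed label fills the gap
        for i in range(a + 1, b):
            filled[i] = observed[a]
    for i in range(obs_idx[-1] + 1, n):
        filled[i] = observed[obs_idx[-1]]
    return filled


def build_label_timeline(assessments: Sequence[CoagAssessment], total_h: float,
                         window_len_h: float = 8.0,
                         patient_id: str = "") -> LabelTimeline:
    """Collapse assessments into contiguous window labels with interpolation.

    Each window's observed label is the label of the latest computable
    assessment inside it; windows with none are interpolated per
    :func:`_interpolate_channel`.
    """
    if total_h < window_len_h:
        raise ValueError("total_h must be at least one window long")
    n = int(math.ceil(total_h / window_len_h))
    sic_obs: list = [None] * n
    dic_obs: list = [None] * n
    observed_any = [False] * n
    for a in assessments:  # time-sorted; later assessments overwrite earlier
        w = int(a.time_h // window_len_h)
        if not (0 <= w < n):
            continue
        if a.sic_positive is not None:
            sic_obs[w] = int(a.sic_positive)
            observed_any[w] = True
        if a.dic_positive is not None:
            dic_obs[w] = int(a.dic_positive)
            observed_any[w] = True

    sic = _interpolate_channel(sic_obs)
    dic = _interpolate_channel(dic_obs)
    entries = []
    for w in range(n):
        if observed_any[w]:
            prov = "observed"
        elif sic[w] is not None or dic[w] is not None:
            prov = "interpolated"
        else:
            prov = "absent"
        entries.append(LabelEntry(w, sic[w], dic[w], prov))
    return LabelTimeline(patient_id, window_len_h, entries)


def label_streams(streams, stays=None, cutoffs: ScoringCutoffs = ScoringCutoffs(),
                  window_len_h: float = 8.0, staleness_h: float = 24.0) -> dict:
    """Assess and label a whole cohort: patient_id -> LabelTimeline.

    ``stays`` maps patient_id to total in-stay hours; when omitted, the last
    event time rounded up to a whole window is used.
    """
    timelines = {}
    for s in streams:
        if stays and s.patient_id in stays:
            total = stays[s.patient_id]
        else:
            total = math.ceil(max(s.last_time(), window_len_h) / window_len_h) * window_len_h
        assessments = assess_stream(s, cutoffs, staleness_h)
        timelines[s.patient_id] = build_label_timeline(
            assessments, total_h=total, window_len_h=window_len_h, patient_id=s.patient_id
        )
    return timelines


def write_timelines(timelines: dict, path, cutoffs: Optional[ScoringCutoffs] = None) -> None:
    """Write label timelines as CSV; cutoffs echoed to a JSON sidecar."""
    frames = [timelines[pid].to_frame() for pid in sorted(timelines)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    if cutoffs is not None:
        sidecar = str(path) + ".cutoffs.json"
        with open(sidecar, "w") as fh:
            fh.write(cutoffs.to_json())


def read_timelines(path) -> dict:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    out = {}
    for pid, grp in frame.groupby("patient_id", sort=False):
        grp = grp.sort_values("window_index")
        window_len = float(grp["window_start_h"].iloc[1] - grp["window_start_h"].iloc[0]) \
            if len(grp) > 1 else 8.0
        entries = [
            LabelEntry(
                int(r.window_index),
                None if pd.isna(r.sic_label) else int(r.sic_label),
                None if pd.isna(r.dic_label) else int(r.dic_label),
                str(r.provenance),
            )
            for r in grp.itertuples()
        ]
        out[str(pid)] = LabelTimeline(str(pid), window_len, entries)
    return out
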