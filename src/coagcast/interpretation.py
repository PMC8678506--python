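"""Model interpretation: occlusion analysis, tree attributions, Lite models.

Occlusion analysis measures the global contribution of one laboratory
variable by re-encoding the evaluation data with that variable *never
observed* — its mask zero everywhere, its values at the fill value, and the
interval feature recomputed so the variable behaves as if the laboratory
never reported it — then re-scoring the trained model without retraining.

Tree-model attributions are delegated to the TreeSHAP implementations built
into xgboost and lightgbm (additive per-sample contributions whose sum plus
the base value equals the model margin); this module exports global ranks,
per-sample rows and dependence tables.

The Lite feature set takes the top-k variables by combined rank (mean of the
attribution and occlusion rank lists) with manual clinical overrides, for
retraining a reduced-panel model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import LabEventStream
from .encoding import EncodingConfig, Normalizer, encode_cohort, windows_to_tabular
from .evaluation import auroc

__all__ = [
    "OcclusionResult",
    "AttributionResult",
    "LiteFeatureSet",
    "occlude_streams",
    "occlude_and_score",
    "occlusion_table",
    "export_attributions",
    "dependence_table",
    "build_lite_set",
]


@dataclass
class OcclusionResult:
    variable: str
    baseline: float
    occluded: float
    model_id: str = ""
    disease: str = ""
    horizon_h: float = np.nan

    @property
    def delta(self) -> float:
        return self.baseline - self.occluded


def occlude_streams(streams: Sequence[LabEventStream], variable: str) -> list:
    """Copy of the cohort with every observation of ``variable`` removed."""
    return [
        LabEventStream(s.patient_id, [ev for ev in s.events if ev.variable != variable])
        for s in streams
    ]


def _score_predictions(model, windows, enc_config, disease, horizon_h, metric):
    from .models import SequenceModel, pack_windows

    if isinstance(model, SequenceModel):
        diseases = tuple(dict.fromkeys(d for d, _ in model.heads))
        horizons = tuple(dict.fromkeys(h for _, h in model.heads))
        packed = pack_windows(windows, enc_config, diseases, horizons)
        col = packed.heads.index((disease, float(horizon_h)))
        risks = model.predict_risks(packed)
        mask = packed.YM[:, col] == 1
        return metric(risks[mask, col], packed.Y[mask, col])
    ps = model.predict(windows)
    rows = ps.rows(disease, float(horizon_h))
    return metric(rows["risk"].to_numpy(), rows["label"].to_numpy())


def occlude_and_score(model, streams, timelines, variable: str,
                      enc_config: EncodingConfig, normalizer: Normalizer,
                      disease: str = "DIC", horizon_h: float = 8.0,
                      metric=auroc) -> OcclusionResult:
    """Metric with and without one variable globally masked (no retraining).

    The occluded dataset keeps the variable in the panel (its mask column
    exists and is all zero; its interval feature accumulates from the series
    start), so trained models accept it unchanged.
    """
    if variable not in enc_config.variables:
        raise ValueError(f"variable {variable!r} not in the configured panel")
    baseline_windows = encode_cohort(streams, timelines, enc_config, normalizer)
    base = _score_predictions(model, baseline_windows, enc_config,
                              disease, horizon_h, metric)
    occluded_windows = encode_cohort(occlude_streams(streams, variable),
                                     timelines, enc_config, normalizer)
    occ = _score_predictions(model, occluded_windows, enc_config,
                             disease, horizon_h, metric)
    return OcclusionResult(variable, float(base), float(occ),
                           getattr(model, "model_id", ""), disease, float(horizon_h))


def occlusion_table(model, streams, timelines, variables: Sequence[str],
                    enc_config: EncodingConfig, normalizer: Normalizer,
                    disease: str = "DIC", horizon_h: float = 8.0) -> pd.DataFrame:
    rows = []
    for v in variables:
        r = occlude_and_score(model, streams, timelines, v, enc_config,
                              normalizer, disease, horizon_h)
        rows.append({"variable": v, "baseline": r.baseline, "occluded": r.occluded,
                     "delta": r.delta, "model": r.model_id, "disease": disease,
                     "horizon_h": horizon_h})
    return pd.DataFrame(rows).sort_values("delta", ascending=False).reset_index(drop=True)


@dataclass
class AttributionResult:
    """Delegated additive attributions for one fitted tree head."""

    global_features: pd.DataFrame   # per engineered feature: mean |contribution|
    global_variables: pd.DataFrame  # aggregated per laboratory variable
    per_sample: pd.DataFrame        # columns = features, plus base_value
    base_value: float
    margins: np.ndarray             # per-sample model margin (= row sums + base)


def export_attributions(tabular_model, windows, disease: str = "DIC",
                        horizon_h: float = 8.0) -> AttributionResult:
    """TreeSHAP attributions from a fitted gradient-boosted tree head.

    Raises for non-tree models (use occlusion analysis for those).
    """
    key = (disease, float(horizon_h))
    if tabular_model.name not in ("xgboost", "lightgbm"):
        raise ValueError(
            f"{tabular_model.name} is not a tree model; use occlusion analysis")
    est = tabular_model.estimators[key]
    X, _ = windows_to_tabular(windows, tabular_model.enc_config,
                              tabular_model.variables)
    Xk = X[:, tabular_model.kept_cols]
    names = tabular_model.feature_names
    if tabular_model.name == "xgboost":
        import xgboost as xgb
        booster = est.get_booster()
        contribs = booster.predict(xgb.DMatrix(Xk), pred_contribs=True)
    else:
        contribs = est.predict(Xk, pred_contrib=True)
    base = float(contribs[0, -1])
    contrib = contribs[:, :-1]
    margins = contribs.sum(axis=1)

    per_sample = pd.DataFrame(contrib, columns=names)
    per_sample["base_value"] = contribs[:, -1]
    global_features = (
        pd.DataFrame({"feature": names,
                      "mean_abs_contribution": np.abs(contrib).mean(axis=0)})
        .sort_values("mean_abs_contribution", ascending=False)
        .reset_index(drop=True)
    )
    var_of = {n: n.split(":")[1] if n.startswith("cell") else n.split(":")[0]
              for n in names}
    agg = {}
    for j, n in enumerate(names):
        agg.setdefault(var_of[n], []).append(j)
    rows = [{"variable": v,
             "mean_abs_contribution": float(np.abs(contrib[:, cols].sum(axis=1)).mean())}
            for v, cols in agg.items()]
    global_variables = (pd.DataFrame(rows)
                        .sort_values("mean_abs_contribution", ascending=False)
                        .reset_index(drop=True))
    global_variables["rank"] = np.arange(1, len(global_variables) + 1)
    return AttributionResult(global_features, global_variables, per_sample,
                             base, margins)


def dependence_table(attr: AttributionResult, windows, tabular_model,
                     feature: str, interaction_feature: Optional[str] = None
                     ) -> pd.DataFrame:
    """(feature value, attribution) pairs, optionally with a second feature's
    values for interaction coloring — the data behind dependence plots."""
    X, _ = windows_to_tabular(windows, tabular_model.enc_config,
                              tabular_model.variables)
    Xk = X[:, tabular_model.kept_cols]
    names = tabular_model.feature_names
    j = names.index(feature)
    out = pd.DataFrame({"value": Xk[:, j],
                        "attribution": attr.per_sample[feature].to_numpy()})
    if interaction_feature is not None:
        out["interaction_value"] = Xk[:, names.index(interaction_feature)]
    return out


@dataclass
class LiteFeatureSet:
    """Reduced variable panel (<= 10) with selection provenance."""

    variables: tuple
    provenance: pd.DataFrame

    def to_json(self) -> str:
        import json
        return json.dumps({"variables": list(self.variables)})


def build_lite_set(attribution_ranks: Mapping[str, float],
                   occlusion_deltas: Mapping[str, float],
                   panel: Sequence[str], k: int = 10,
                   include: Sequence[str] = (), exclude: Sequence[str] = ()
                   ) -> LiteFeatureSet:
    """Top-k variables by mean of the two rank lists, with manual overrides.

    ``attribution_ranks`` maps variable -> rank (1 = most important);
    ``occlusion_deltas`` maps variable -> AUROC drop when occluded (larger =
    more important).  Manual ``include`` entries are forced in (error when
    not in the panel); ``exclude`` entries are removed before ranking.
    """
    for v in include:
        if v not in panel:
            raise ValueError(f"manual include {v!r} not in panel")
    candidates = [v for v in panel if v not in exclude]
    occ_order = sorted(candidates, key=lambda v: -occlusion_deltas.get(v, -np.inf))
    occ_rank = {v: i + 1 for i, v in enumerate(occ_order)}
    n = len(candidates)
    combined = {
        v: 0.5 * (attribution_ranks.get(v, n) + occ_rank[v]) for v in candidates
    }
    ordered = sorted(candidates, key=lambda v: (combined[v], v))
    selected = list(include) + [v for v in ordered if v not in include]
    selected = selected[:min(k, 10)]
    prov = pd.DataFrame({
        "variable": candidates,
        "attribution_rank": [attribution_ranks.get(v, np.nan) for v in candidates],
        "occlusion_rank": [occ_rank[v] for v in candidates],
        "combined_rank": [combined[v] for v in candidates],
        "manual_include": [v in include for v in candidates],
        "selected": [v in selected for v in candidates],
    }).sort_values("combined_rank").reset_index(drop=True)
    return LiteFeatureSet(tuple(selected), prov)
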