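"""End-to-end orchestration: generate -> label -> encode -> train -> evaluate
-> interpret, with reproducible artifacts.

Each stage reads its inputs from the run directory, writes its outputs plus a
manifest (config hash, input hashes, seed), and is skipped on re-run when
nothing it depends on changed.  All randomness derives from the single run
seed; two runs with identical configuration produce byte-identical
evaluation reports.

Splits are made at the patient level (70/10/20 by default): windows of one
patient never cross splits, and normalization statistics are learned from
training patients only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (CohortConfig, generate_cohort, read_cohort, read_truth,
                     write_cohort, write_truth)
from .encoding import (DISEASES, EncodingConfig, Normalizer, encode_cohort,
                       read_windows, write_windows)
from .evaluation import alarm_metrics, horizon_report
from .interpretation import (build_lite_set, export_attributions, occlusion_table)
from .models import (SEQUENCE_CELLS, TABULAR_MODELS, PredictionSet,
                     SequenceModel, SequenceModelConfig, TabularModel,
                     pack_windows, train_tabular_baselines)
from .scoring import ScoringCutoffs, label_streams, read_timelines, write_timelines

__all__ = ["RunConfig", "split_patients", "run", "STAGES", "sweep_window"]

log = logging.getLogger("coagcast")

STAGES = ("generate", "label", "encode", "train", "evaluate", "interpret")


@dataclass
class RunConfig:
    """Composition of all stage configurations plus the global seed."""

    outdir: str = "coagcast_run"
    seed: int = 0
    n_patients: int = 200
    models: tuple = ("logreg", "xgboost")
    diseases: tuple = DISEASES
    split_fractions: tuple = (0.7, 0.1, 0.2)
    cohort: dict = field(default_factory=dict)       # CohortConfig overrides
    cutoffs: dict = field(default_factory=dict)      # ScoringCutoffs overrides
    encoding: dict = field(default_factory=dict)     # EncodingConfig overrides
    sequence: dict = field(default_factory=dict)     # SequenceModelConfig overrides
    staleness_h: float = 24.0
    eval_resamples: int = 1000
    alarm_horizon_h: float = 8.0
    lite_k: int = 10

    def __post_init__(self) -> None:
        # fail fast: constructing sub-configs validates them before any compute
        self.cohort_config()
        self.scoring_cutoffs()
        self.encoding_config()
        for m in self.models:
            if m not in TABULAR_MODELS + SEQUENCE_CELLS:
                raise ValueError(f"unknown model {m!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.cohort)
        kw.setdefault("seed", self.seed)
        return CohortConfig(n_patients=self.n_patients, **kw)

    def scoring_cutoffs(self) -> ScoringCutoffs:
        return ScoringCutoffs(**self.cutoffs)

    def encoding_config(self) -> EncodingConfig:
        return EncodingConfig(**self.encoding)

    def sequence_config(self, cell: str) -> SequenceModelConfig:
        kw = dict(self.sequence)
        kw.setdefault("seed", self.seed + 101)
        return SequenceModelConfig(cell=cell, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        for key in ("models", "diseases", "split_fractions"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_patients(patient_ids: Sequence[str], fractions=(0.7, 0.1, 0.2),
                   seed: int = 0):
    """Patient-disjoint train/valid/test split, deterministic given seed.

    Sizes follow the largest-remainder rounding rule; every split must be
    nonempty.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(patient_ids)
    n = len(ids)
    exact = [f * n for f in fractions]
    sizes = [int(e) for e in exact]
    rem = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: exact[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    if min(sizes) == 0:
        raise ValueError(f"n={n} too small for nonempty splits {fractions}")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    train = shuffled[:sizes[0]]
    valid = shuffled[sizes[0]:sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return train, valid, test


# ---------------------------------------------------------------------------
# manifests

def _hash_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()


def _hash_file(path: Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


def _stage_manifest(outdir: Path, stage: str) -> Path:
    return outdir / f"manifest_{stage}.json"


def _write_manifest(outdir: Path, stage: str, config_hash: str,
                    inputs: dict, outputs: Sequence[str]) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config_hash,
        "input_hashes": inputs,
        "outputs": list(outputs),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _stage_manifest(outdir, stage).write_text(json.dumps(manifest, indent=1))


def _stage_fresh(outdir: Path, stage: str, config_hash: str, inputs: dict) -> bool:
    mpath = _stage_manifest(outdir, stage)
    if not mpath.exists():
        return False
    try:
        m = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if m.get("config_hash") != config_hash or m.get("input_hashes") != inputs:
        return False
    return all((outdir / o).exists() for o in m.get("outputs", ()))


def _require(outdir: Path, filename: str, producing_stage: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing stage input {p}; run the '{producing_stage}' stage first")
    return p


def _config_hash(config: RunConfig, keys: Sequence[str]) -> str:
    sub = {k: getattr(config, k) for k in keys}
    return _hash_bytes(json.dumps(sub, sort_keys=True, default=str).encode())


# ---------------------------------------------------------------------------
# stages

def _stage_generate(config: RunConfig, outdir: Path) -> None:
    chash = _config_hash(config, ["seed", "n_patients", "cohort"])
    if _stage_fresh(outdir, "generate", chash, {}):
        log.info("generate: up to date, skipped")
        return
    streams, trajs = generate_cohort(config.cohort_config())
    write_cohort(streams, outdir / "cohort.csv")
    write_truth(trajs, outdir / "truth.csv")
    _write_manifest(outdir, "generate", chash, {}, ["cohort.csv", "truth.csv"])
    log.info("generate: %d patients", len(streams))


def _stage_label(config: RunConfig, outdir: Path) -> None:
    cohort_path = _require(outdir, "cohort.csv", "generate")
    inputs = {"cohort.csv": _hash_file(cohort_path)}
    chash = _config_hash(config, ["cutoffs", "staleness_h", "encoding"])
    if _stage_fresh(outdir, "label", chash, inputs):
        log.info("label: up to date, skipped")
        return
    streams = read_cohort(cohort_path)
    truth_path = outdir / "truth.csv"
    stays = None
    if truth_path.exists():
        stays = {tr.patient_id: tr.stay_h for tr in read_truth(truth_path)}
    cutoffs = config.scoring_cutoffs()
    window_len = config.encoding_config().slide_step_h
    timelines = label_streams(streams, stays=stays, cutoffs=cutoffs,
                              window_len_h=window_len,
                              staleness_h=config.staleness_h)
    write_timelines(timelines, outdir / "labels.csv", cutoffs)
    _write_manifest(outdir, "label", chash, inputs, ["labels.csv"])
    log.info("label: %d patients labeled", len(timelines))


def _stage_encode(config: RunConfig, outdir: Path) -> None:
    cohort_path = _require(outdir, "cohort.csv", "generate")
    labels_path = _require(outdir, "labels.csv", "label")
    inputs = {p.name: _hash_file(p) for p in (cohort_path, labels_path)}
    chash = _config_hash(config, ["seed", "encoding", "split_fractions"])
    if _stage_fresh(outdir, "encode", chash, inputs):
        log.info("encode: up to date, skipped")
        return
    streams = read_cohort(cohort_path)
    timelines = read_timelines(labels_path)
    enc = config.encoding_config()
    train_ids, valid_ids, test_ids = split_patients(
        [s.patient_id for s in streams], config.split_fractions, config.seed + 7)
    (outdir / "split.json").write_text(json.dumps(
        {"train": train_ids, "valid": valid_ids, "test": test_ids}))
    by_id = {s.patient_id: s for s in streams}
    normalizer = Normalizer.fit([by_id[p] for p in train_ids], enc.variables)
    outputs = ["split.json", "norm.json"]
    (outdir / "norm.json").write_text(normalizer.to_json())
    for name, ids in [("train", train_ids), ("valid", valid_ids), ("test", test_ids)]:
        windows = encode_cohort([by_id[p] for p in ids], timelines, enc, normalizer)
        write_windows(windows, outdir / f"windows_{name}.jsonl")
        outputs.append(f"windows_{name}.jsonl")
        log.info("encode: %s split, %d windows", name, len(windows))
    _write_manifest(outdir, "encode", chash, inputs, outputs)


def _stage_train(config: RunConfig, outdir: Path) -> None:
    paths = {name: _require(outdir, f"windows_{name}.jsonl", "encode")
             for name in ("train", "valid", "test")}
    inputs = {p.name: _hash_file(p) for p in paths.values()}
    chash = _config_hash(config, ["seed", "models", "diseases", "sequence", "encoding"])
    if _stage_fresh(outdir, "train", chash, inputs):
        log.info("train: up to date, skipped")
        return
    enc = config.encoding_config()
    normalizer = Normalizer.from_json((outdir / "norm.json").read_text())
    variables = normalizer.kept(enc.variables)
    splits = {name: read_windows(p) for name, p in paths.items()}
    (outdir / "models").mkdir(exist_ok=True)
    frames = []
    training_log = {}
    for name in config.models:
        t0 = time.time()
        if name in TABULAR_MODELS:
            model = train_tabular_baselines(
                splits["train"] + splits["valid"], enc, variables, name,
                diseases=config.diseases, seed=config.seed + 31)
            ps = model.predict(splits["test"])
            if name == "xgboost":
                for (dis, h), est in model.estimators.items():
                    est.get_booster().save_model(
                        str(outdir / "models" / f"xgboost_{dis}_{int(h)}.json"))
        else:
            scfg = config.sequence_config(name)
            train_p = pack_windows(splits["train"], enc, config.diseases)
            valid_p = pack_windows(splits["valid"], enc, config.diseases)
            model = SequenceModel(scfg, len(variables), train_p.heads)
            training_log[name] = model.fit(train_p, valid_p)
            ps = model.predict(pack_windows(splits["test"], enc, config.diseases))
            np.savez(outdir / "models" / f"{name}.npz",
                     **{k: p.data for k, p in model.params.items()})
        frames.append(ps.frame)
        log.info("train: %s done in %.1fs", name, time.time() - t0)
    pred = pd.concat(frames, ignore_index=True)
    pred.to_json(outdir / "predictions_test.jsonl", orient="records", lines=True)
    (outdir / "training_log.json").write_text(json.dumps(training_log))
    _write_manifest(outdir, "train", chash, inputs,
                    ["predictions_test.jsonl", "training_log.json"])


def _stage_evaluate(config: RunConfig, outdir: Path) -> None:
    pred_path = _require(outdir, "predictions_test.jsonl", "train")
    labels_path = _require(outdir, "labels.csv", "label")
    inputs = {p.name: _hash_file(p) for p in (pred_path, labels_path)}
    chash = _config_hash(config, ["seed", "eval_resamples", "alarm_horizon_h",
                                  "encoding"])
    if _stage_fresh(outdir, "evaluate", chash, inputs):
        log.info("evaluate: up to date, skipped")
        return
    pred = pd.read_json(pred_path, orient="records", lines=True,
                        dtype={"patient_id": str})
    sets = [PredictionSet(m, g.reset_index(drop=True))
            for m, g in pred.groupby("model", sort=True)]
    report = horizon_report(sets, n_resamples=config.eval_resamples,
                            seed=config.seed + 77)
    report.to_csv(outdir / "eval_report.csv")
    enc = config.encoding_config()
    timelines = read_timelines(labels_path)
    sweeps = []
    for ps in sets:
        for dis in config.diseases:
            if not len(ps.rows(dis, config.alarm_horizon_h)):
                continue
            sw = alarm_metrics(ps, timelines, dis, config.alarm_horizon_h,
                               enc.sampling_window_h)
            sw.insert(0, "disease", dis)
            sw.insert(0, "model", ps.model_id)
            sweeps.append(sw)
    if sweeps:
        pd.concat(sweeps, ignore_index=True).to_csv(
            outdir / "threshold_sweep.csv", index=False, float_format="%.6f")
    _write_manifest(outdir, "evaluate", chash, inputs,
                    ["eval_report.csv"] + (["threshold_sweep.csv"] if sweeps else []))
    log.info("evaluate: report written")


def _stage_interpret(config: RunConfig, outdir: Path) -> None:
    if "xgboost" not in config.models:
        log.info("interpret: skipped (requires the xgboost model in the roster)")
        return
    for f, stage in [("cohort.csv", "generate"), ("labels.csv", "label"),
                     ("windows_test.jsonl", "encode"),
                     ("predictions_test.jsonl", "train")]:
        _require(outdir, f, stage)
    inputs = {"predictions_test.jsonl": _hash_file(outdir / "predictions_test.jsonl")}
    chash = _config_hash(config, ["seed", "models", "lite_k", "encoding"])
    if _stage_fresh(outdir, "interpret", chash, inputs):
        log.info("interpret: up to date, skipped")
        return
    enc = config.encoding_config()
    normalizer = Normalizer.from_json((outdir / "norm.json").read_text())
    variables = normalizer.kept(enc.variables)
    # deterministic refit from the persisted splits (same data, same seed as
    # the train stage) — equivalent to reloading the saved boosters
    splits = {n: read_windows(outdir / f"windows_{n}.jsonl")
              for n in ("train", "valid", "test")}
    model = train_tabular_baselines(splits["train"] + splits["valid"], enc,
                                    variables, "xgboost",
                                    diseases=config.diseases,
                                    seed=config.seed + 31)
    split_ids = json.loads((outdir / "split.json").read_text())
    streams = [s for s in read_cohort(outdir / "cohort.csv")
               if s.patient_id in set(split_ids["test"])]
    timelines = read_timelines(outdir / "labels.csv")
    disease = "DIC" if "DIC" in config.diseases else config.diseases[0]
    horizon = enc.horizons_h[0]
    occ = occlusion_table(model, streams, timelines, variables, enc, normalizer,
                          disease, horizon)
    occ.to_csv(outdir / "occlusion.csv", index=False, float_format="%.6f")
    attr = export_attributions(model, splits["test"], disease, horizon)
    attr.global_variables.to_csv(outdir / "attributions_global.csv", index=False,
                                 float_format="%.6f")
    attr.per_sample.iloc[:200].to_csv(outdir / "attributions_samples.csv",
                                      index=False, float_format="%.6f")
    ranks = dict(zip(attr.global_variables["variable"],
                     attr.global_variables["rank"]))
    deltas = dict(zip(occ["variable"], occ["delta"]))
    lite = build_lite_set(ranks, deltas, variables, k=config.lite_k)
    (outdir / "lite.json").write_text(lite.to_json())
    _write_manifest(outdir, "interpret", chash, inputs,
                    ["occlusion.csv", "attributions_global.csv", "lite.json"])
    log.info("interpret: occlusion + attributions + lite set written")


_STAGE_FNS = {
    "generate": _stage_generate,
    "label": _stage_label,
    "encode": _stage_encode,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "interpret": _stage_interpret,
}


def run(config: RunConfig, stages: Optional[Sequence[str]] = None) -> Path:
    """Run pipeline stages (a prefix-closed subset of the DAG) and return the
    artifact directory."""
    if stages is None:
        stages = STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    try:
        for stage in STAGES:
            if stage in stages:
                _STAGE_FNS[stage](config, outdir)
    finally:
        log.removeHandler(fh)
        fh.close()
    return outdir


def sweep_window(config: RunConfig, window_lengths=(8.0, 24.0, 48.0)) -> pd.DataFrame:
    """Sampling-window pre-experiment: rerun the pipeline with different
    window lengths and collect the 8 h-horizon AUROC per disease."""
    from .evaluation import auroc

    rows = []
    base_out = Path(config.outdir)
    for w in window_lengths:
        sub = dataclasses.replace(
            config,
            outdir=str(base_out / f"window_{int(w)}h"),
            encoding={**config.encoding, "sampling_window_h": w,
                      "horizons_h": (8.0,)},
            models=("xgboost",),
        )
        run(sub, stages=("generate", "label", "encode", "train"))
        pred = pd.read_json(Path(sub.outdir) / "predictions_test.jsonl",
                            orient="records", lines=True)
        for dis, g in pred[pred["label"].notna()].groupby("disease"):
            try:
                a = auroc(g["risk"].to_numpy(), g["label"].to_numpy())
            except ValueError:
                a = np.nan
            rows.append({"sampling_window_h": w, "disease": dis, "auroc": a})
    frame = pd.DataFrame(rows)
    frame.to_csv(base_out / "window_sweep.csv", index=False, float_format="%.6f")
    return frame
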