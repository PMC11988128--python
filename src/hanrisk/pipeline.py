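"""End-to-end experiment orchestration.

One config drives the whole chain: simulate a synthetic SOEP cohort ->
prepare documents and the stratified 60/20/20 split -> train word embeddings
on the training fold only -> train each requested architecture -> evaluate
on the held-out test fold with bootstrap intervals -> paired difference
tests against the hierarchical attention model.  All stages share the split
and the frozen training-fold embeddings, and every random draw derives from
the single experiment seed, so a rerun of the same config reproduces the
result bundle byte for byte.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .cohort import Document, prepare_documents, stratified_split
from .embeddings import train_embeddings
from .metrics import (PredictionSet, auprc, auroc, bootstrap_diff_test, brier,
                      calibration_curve, evaluate_predictions, DEFAULT_CUTOFF)
from .networks import ModelConfig, build_model, predict_proba
from .synthetic import GeneratorConfig, generate_corpus
from .training import TrainConfig, train

__all__ = ["ExperimentConfig", "run_experiment", "make_report",
           "validate_report", "REPORT_SCHEMA"]


@dataclass
class ExperimentConfig:
    """One section per stage; the global seed feeds every stage."""

    seed: int = 0
    generator: dict[str, Any] = field(default_factory=dict)
    prep: dict[str, Any] = field(default_factory=dict)
    embedding: dict[str, Any] = field(default_factory=dict)
    models: list[dict[str, Any]] = field(
        default_factory=lambda: [{"kind": "han_text"},
                                 {"kind": "han_combined"}])
    train: dict[str, Any] = field(default_factory=dict)
    evaluation: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(5)
        names = ("generator", "split", "embedding", "train", "evaluation")
        return {n: int(s % (2 ** 31)) for n, s in zip(names, state)}


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage's name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r}: {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full experiment; returns the JSON-serialisable bundle."""
    seeds = config.stage_seeds()

    with _stage("simulate"):
        gen_cfg = GeneratorConfig(seed=seeds["generator"], **config.generator)
        records = generate_corpus(gen_cfg)

    with _stage("prepare"):
        docs = prepare_documents(records, **config.prep)
        split = stratified_split(docs, seed=seeds["split"])
        folds: dict[str, list[Document]] = {"train": [], "tune": [], "test": []}
        for d in docs:
            folds[split.assignment[d.patient_id]].append(d)

    with _stage("train-embeddings"):
        emb_kw = {"dim": 64, "window": 5, "min_count": 5, "epochs": 3,
                  **config.embedding}
        embedding = train_embeddings(folds["train"], seed=seeds["embedding"],
                                     **emb_kw)

    eval_kw = {"cutoff": DEFAULT_CUTOFF, "n_boot": 1000,
               **config.evaluation}
    train_cfg = TrainConfig(**config.train)

    bundle: dict[str, Any] = {
        "seed": config.seed,
        "n_patients_generated": len(records),
        "n_documents": len(docs),
        "fold_sizes": {k: len(v) for k, v in folds.items()},
        "fold_cases": {k: int(sum(d.label for d in v))
                       for k, v in folds.items()},
        "vocabulary_size": len(embedding.vocab),
        "models": {},
        "comparisons": {},
        "calibration": {},
    }

    predictions: dict[str, PredictionSet] = {}
    for mi, spec in enumerate(config.models):
        kind = spec["kind"]
        with _stage(f"train[{kind}]"):
            overrides = {k: v for k, v in spec.items() if k != "kind"}
            cfg = ModelConfig(kind=kind, embed_dim=embedding.dim,
                              seed=seeds["train"] % (2 ** 20) + mi,
                              **overrides)
            model = build_model(cfg)
            model, history = train(model, folds["train"], folds["tune"],
                                   embedding, hyperparams=train_cfg,
                                   seed=cfg.seed)
        with _stage(f"evaluate[{kind}]"):
            # test-fold labels are read here for the first time
            probs = predict_proba(model, folds["test"], embedding)
            pred = PredictionSet([d.patient_id for d in folds["test"]],
                                 np.array([d.label for d in folds["test"]]),
                                 probs)
            predictions[kind] = pred
            report = evaluate_predictions(pred, cutoff=eval_kw["cutoff"],
                                          n_boot=eval_kw["n_boot"],
                                          seed=seeds["evaluation"])
            bundle["models"][kind] = {
                "report": report.as_dict(),
                "history": history,
            }
            trimmed = pred.probabilities <= 0.30
            if len(pred) >= 20 and trimmed.any():
                curve = calibration_curve(pred)
                bundle["calibration"][kind] = [[float(a), float(b)]
                                               for a, b in curve]

    with _stage("compare"):
        reference = "han_text" if "han_text" in predictions else None
        metric_fns = {"auroc": auroc, "auprc": auprc, "brier": brier}
        if reference is not None:
            for kind, pred in predictions.items():
                if kind == reference:
                    continue
                key = f"{reference}_vs_{kind}"
                bundle["comparisons"][key] = {}
                for mname, fn in metric_fns.items():
                    d, lo, hi, sig = bootstrap_diff_test(
                        predictions[reference], pred, fn,
                        n_boot=eval_kw["n_boot"], seed=seeds["evaluation"])
                    bundle["comparisons"][key][mname] = {
                        "diff": d, "ci_low": lo, "ci_high": hi,
                        "significant": sig,
                    }
    bundle["_predictions"] = {
        kind: {"patient_ids": pred.patient_ids,
               "labels": pred.labels.tolist(),
               "probabilities": pred.probabilities.tolist()}
        for kind, pred in predictions.items()
    }
    return bundle


# ------------------------------------------------------------------ report
REPORT_SCHEMA: dict = {
    "required": ["seed", "n_documents", "fold_sizes", "models", "comparisons"],
    "model_metrics": ["auroc", "auprc", "brier", "brier_x100", "sensitivity",
                      "specificity", "ppv", "npv"],
    "triple": ["point", "ci_low", "ci_high"],
    "comparison": ["diff", "ci_low", "ci_high", "significant"],
}


def validate_report(report: dict) -> None:
    """Structural validation of a metrics report against REPORT_SCHEMA."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
    for kind, entry in report["models"].items():
        rep = entry["report"]
        for metric in REPORT_SCHEMA["model_metrics"]:
            if metric not in rep:
                raise ValueError(f"model {kind}: missing metric {metric!r}")
            for part in REPORT_SCHEMA["triple"]:
                if part not in rep[metric]:
                    raise ValueError(
                        f"model {kind}, metric {metric}: missing {part!r}")
    for key, entry in report["comparisons"].items():
        for metric, d in entry.items():
            for part in REPORT_SCHEMA["comparison"]:
                if part not in d:
                    raise ValueError(
                        f"comparison {key}, {metric}: missing {part!r}")


def make_report(bundle: dict, out_dir: str | Path) -> list[Path]:
    """Write metrics JSON, discrimination/threshold CSV tables, prediction
    CSVs and calibration-curve data.  Brier is rendered x100 in tables."""
    if not bundle or not bundle.get("models"):
        raise ValueError("cannot write a report from an empty result bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    public = {k: v for k, v in bundle.items() if not k.startswith("_")}
    validate_report(public)
    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(public, sort_keys=True, indent=2))
    written.append(metrics_path)

    def fmt(t):
        return f"{t['point']:.4g} ({t['ci_low']:.4g}, {t['ci_high']:.4g})"

    disc_path = out / "discrimination.csv"
    with open(disc_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Model", "AUROC", "AUPRC", "Brier Score (x100)"])
        for kind, entry in bundle["models"].items():
            r = entry["report"]
            w.writerow([kind, fmt(r["auroc"]), fmt(r["auprc"]),
                        fmt(r["brier_x100"])])
    written.append(disc_path)

    thr_path = out / "threshold_metrics.csv"
    with open(thr_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Model", "Sensitivity", "Specificity", "PPV", "NPV"])
        for kind, entry in bundle["models"].items():
            r = entry["report"]
            w.writerow([kind, fmt(r["sensitivity"]), fmt(r["specificity"]),
                        fmt(r["ppv"]), fmt(r["npv"])])
    written.append(thr_path)

    for kind, points in bundle.get("calibration", {}).items():
        cal_path = out / f"calibration_{kind}.csv"
        with open(cal_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["predicted", "observed"])
            w.writerows(points)
        written.append(cal_path)

    for kind, preds in bundle.get("_predictions", {}).items():
        p_path = out / f"predictions_{kind}.csv"
        with open(p_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "label", "probability"])
            for pid, y, p in zip(preds["patient_ids"], preds["labels"],
                                 preds["probabilities"]):
                w.writerow([pid, y, repr(p)])
        written.append(p_path)
    return written
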