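"""End-to-end orchestration: generate -> normalize -> split -> train ->
evaluate -> applicability domain -> sensitivity, as one seeded run.

One master seed is fanned out (via numpy's SeedSequence) into independent
stage seeds for generation, the split and the swarm, so a single integer
reproduces the whole run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, preprocessing, training
from .datasets import Dataset, GeneratorConfig, generate_dataset
from .elm import ELMModel, predict

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; nested stage configs keep their own fields."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    trainer: training.TrainerConfig = field(default_factory=training.TrainerConfig)
    train_fraction: float = 0.75
    norm_scope: str = "full"
    seed: int = 42

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        kwargs = dict(doc)
        if "generator" in kwargs:
            kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
        if "trainer" in kwargs:
            t = dict(kwargs["trainer"])
            if "pso" in t:
                from .pso import PSOConfig
                t["pso"] = PSOConfig(**t["pso"])
            kwargs["trainer"] = training.TrainerConfig(**t)
        return cls(**kwargs)

    def stage_seeds(self) -> dict[str, int]:
        gen, spl, trn = np.random.SeedSequence(self.seed).generate_state(3)
        # keep seeds in signed-int range for serializability everywhere
        return {"generate": int(gen) % 2**31, "split": int(spl) % 2**31,
                "train": int(trn) % 2**31}


@dataclass
class RunReport:
    """Run summary: metrics per phase, domain flags, sensitivity, history."""

    config: dict
    seeds: dict[str, int]
    metrics: dict[str, dict]
    ad_summary: dict
    sensitivity: dict[str, float]
    fitness_history: list[float]
    artifacts: dict[str, str]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _config_echo(config: PipelineConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["trainer"]["pso"]["position_bounds"] = list(
        np.asarray(doc["trainer"]["pso"]["position_bounds"], float).ravel())
    return doc


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute every stage, write flat-file artifacts, return the report.

    Writes ``dataset.csv``, ``model.json``, ``report.json``, ``williams.csv``,
    ``deviations.csv`` and ``sensitivity.csv`` under ``out_dir``. Idempotent
    for identical configs; on any stage failure partial outputs are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    seeds = config.stage_seeds()
    stage = "setup"
    try:
        stage = "generate"
        t0 = time.perf_counter()
        gen_cfg = dataclasses.replace(config.generator, seed=seeds["generate"])
        data = generate_dataset(gen_cfg)
        dataset_path = out / "dataset.csv"
        data.to_csv(dataset_path)
        written.append(dataset_path)
        log.info("generate: %d rows in %.2fs", data.n_samples,
                 time.perf_counter() - t0)

        stage = "split"
        split = preprocessing.split(data.n_samples, config.train_fraction,
                                    seed=seeds["split"])

        stage = "normalize"
        params = preprocessing.fit_normalizer(data, config.norm_scope, split)
        norm = preprocessing.normalize(data, params)

        stage = "train"
        t0 = time.perf_counter()
        trainer_cfg = dataclasses.replace(config.trainer, seed=seeds["train"])
        model, train_report = training.train(data, split, params, trainer_cfg)
        log.info("train: best fitness %.4g in %.2fs", train_report.best_fitness,
                 time.perf_counter() - t0)
        model_path = out / "model.json"
        _write_model(model_path, model, params, trainer_cfg)
        written.append(model_path)

        stage = "evaluate"
        pred_norm = predict(model, norm.features)
        pred = preprocessing.denormalize_target(pred_norm, params)
        phase = np.full(data.n_samples, "test", dtype=object)
        phase[split.train_indices] = "train"
        metrics = {
            "train": diagnostics.fit_metrics(
                data.target[split.train_indices],
                pred[split.train_indices], "train"),
            "test": diagnostics.fit_metrics(
                data.target[split.test_indices],
                pred[split.test_indices], "test"),
            "total": diagnostics.fit_metrics(data.target, pred, "total"),
        }
        deviations = diagnostics.relative_deviation(data.target, pred)
        dev_path = out / "deviations.csv"
        pd.DataFrame({
            "row": np.arange(data.n_samples), "phase": phase,
            "actual": data.target, "predicted": pred,
            "deviation_percent": deviations,
        }).to_csv(dev_path, index=False, lineterminator="\n")
        written.append(dev_path)

        stage = "applicability_domain"
        ad = diagnostics.williams(
            norm.features[split.train_indices], norm.features,
            data.target - pred, metrics["total"].rmse)
        ad_path = out / "williams.csv"
        pd.DataFrame({
            "row": np.arange(data.n_samples), "phase": phase,
            "leverage": ad.leverages, "std_residual": ad.std_residuals,
            "flag": ad.flags,
        }).to_csv(ad_path, index=False, lineterminator="\n")
        written.append(ad_path)

        stage = "sensitivity"
        sens = diagnostics.relevancy_factors(data)
        sens_path = out / "sensitivity.csv"
        pd.DataFrame({
            "feature": list(sens.relevancy),
            "relevancy": list(sens.relevancy.values()),
        }).to_csv(sens_path, index=False, lineterminator="\n")
        written.append(sens_path)

        stage = "report"
        report = RunReport(
            config=_config_echo(config),
            seeds=seeds,
            metrics={k: m.to_dict() for k, m in metrics.items()},
            ad_summary={
                "warning_leverage": ad.warning_leverage,
                "counts": ad.counts(),
                "suspicious_rows": [
                    {"row": int(i), "phase": str(phase[i]), "flag": ad.flags[i]}
                    for i in ad.suspicious_rows()],
            },
            sensitivity=sens.relevancy,
            fitness_history=[float(f) for f in train_report.fitness_history],
            artifacts={p.stem: str(p) for p in written},
        )
        report_path = out / "report.json"
        report.artifacts["report"] = str(report_path)
        report.to_json(report_path)
        return report
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_model(path: Path, model: ELMModel,
                 params: preprocessing.NormalizationParams,
                 trainer_cfg: training.TrainerConfig) -> None:
    doc = model.to_dict()
    doc["normalization"] = {
        "feature_min": params.feature_min.tolist(),
        "feature_max": params.feature_max.tolist(),
        "target_min": params.target_min,
        "target_max": params.target_max,
        "scope": params.scope,
    }
    doc["trainer"] = {"n_hidden": trainer_cfg.n_hidden,
                      "activation": trainer_cfg.activation,
                      "ridge": trainer_cfg.ridge,
                      "seed": trainer_cfg.seed}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
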