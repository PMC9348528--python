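"""End-to-end pipeline: simulate -> fit kinetics -> train surrogate -> optimize.

Every stage seed is derived deterministically from the single pipeline
seed, so the whole run is a pure function of its configuration. Each
stage artifact embeds a hash of that configuration; the report renderer
refuses to mix artifacts from different configurations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import kinetics as kin
from .datamodel import load_doe_design, write_records
from .exceptions import ValidationError
from .optimizer import GAConfig, fitness_terms, optimize_formulation
from .surrogate import (
    AugmentationConfig,
    ReleaseSurrogate,
    SurrogateConfig,
    compare_augmentation_vs_cv,
    evaluate_metrics,
    mean_relative_error,
    prepare_surrogate_data,
    records_to_xy,
    select_hidden_units,
    train_surrogate,
)
from .synthetic import EffectSpec, generate_dataset

logger = logging.getLogger("nanorelease.pipeline")


@dataclass
class PipelineConfig:
    seed: int = 1
    replicates: int = 3
    effects: Optional[EffectSpec] = None
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    hidden_candidates: tuple = tuple(range(2, 8))
    leakage: bool = True
    run_sweep: bool = True
    outdir: Optional[str] = None


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    return obj


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    dataset: Optional[dict] = None
    kinetics: Optional[dict] = None
    sweep: Optional[dict] = None
    comparison: Optional[dict] = None
    surrogate: Optional[dict] = None
    optimization: Optional[dict] = None

    SECTIONS = ("dataset", "kinetics", "sweep", "comparison", "surrogate",
                "optimization")

    def missing_sections(self) -> list:
        return [s for s in self.SECTIONS if getattr(self, s) is None]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(_jsonable(self), indent=1, sort_keys=True))


def _stamp(section: dict, chash: str) -> dict:
    section["config_hash"] = chash
    return section


def run_pipeline(config: Optional[PipelineConfig] = None) -> PipelineReport:
    """Execute all stages in order; see module docstring for determinism."""
    cfg = config if config is not None else PipelineConfig()
    chash = config_hash(cfg)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config_hash=chash, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    seed_data, seed_aug, seed_train, seed_ga = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=4))

    # --- stage 1: synthetic dataset -------------------------------------
    t0 = time.perf_counter()
    design = load_doe_design()
    dataset = generate_dataset(design, effects=cfg.effects,
                               replicates=cfg.replicates, seed=seed_data)
    frame = dataset.to_frame()
    report.dataset = _stamp({
        "n_records": len(dataset.records),
        "replicates": cfg.replicates,
        "seed": seed_data,
        "response_means": {c: float(frame[c].mean()) for c in
                           ("br_percent", "trmax_h", "rtrmax_percent", "le_percent")},
    }, chash)
    if outdir:
        write_records(dataset.records, outdir / "records.csv",
                      curves_path=outdir / "curves.csv")
    logger.info("simulate: %d records in %.2fs", len(dataset.records),
                time.perf_counter() - t0)

    # --- stage 2: kinetics on replicate-1 curves ------------------------
    t0 = time.perf_counter()
    rows = []
    for rec in dataset.records:
        if rec.replicate != 1 or rec.curve is None:
            continue
        comp = kin.compare_models(rec.curve)
        peppas = next((f for f in comp.fits if f.model_name == "korsmeyer_peppas"), None)
        row = {"run_code": rec.run_code, "best_model": comp.best.model_name,
               "best_r2": comp.best.r_squared}
        if peppas is not None:
            row.update(peppas_k=peppas.params["k"], peppas_n=peppas.params["n"],
                       peppas_r2=peppas.r_squared,
                       transport=kin.classify_transport(peppas.params["n"]).label)
        rows.append(row)
    ktable = pd.DataFrame(rows)
    report.kinetics = _stamp({"per_run": ktable.to_dict("records")}, chash)
    if outdir:
        ktable.to_csv(outdir / "kinetics.csv", index=False)
    logger.info("fit-kinetics: %d runs in %.2fs", len(rows), time.perf_counter() - t0)

    # --- stage 3: surrogate protocol ------------------------------------
    t0 = time.perf_counter()
    scfg = replace(cfg.surrogate, seed=seed_train)
    aug = replace(cfg.augmentation, seed=seed_aug)
    data = prepare_surrogate_data(dataset.records, augmentation=aug,
                                  config=scfg, leakage=cfg.leakage)
    if cfg.run_sweep:
        best_h, sweep_table = select_hidden_units(data, cfg.hidden_candidates, scfg)
        report.sweep = _stamp({"best_hidden_units": best_h,
                               "table": sweep_table.to_dict("records")}, chash)
        if outdir:
            sweep_table.to_csv(outdir / "hidden_unit_sweep.csv", index=False)
    else:
        best_h = scfg.hidden_units
        report.sweep = _stamp({"best_hidden_units": best_h, "table": []}, chash)

    comp = compare_augmentation_vs_cv(dataset.records, augmentation=aug,
                                      config=replace(scfg, hidden_units=best_h),
                                      leakage=cfg.leakage)
    report.comparison = _stamp({
        "gaussian_noise": {"mse": comp.gaussian.mse, "r2": comp.gaussian.r2},
        "cross_validation": {"mse": comp.cross_validation.mse,
                             "r2": comp.cross_validation.r2},
        "winner": comp.winner,
    }, chash)

    final_cfg = replace(scfg, hidden_units=best_h)
    test_records = [r for r in dataset.records if r.replicate != 1]
    Xtr = data.X_train  # already normalized per protocol
    surro = ReleaseSurrogate(
        *records_to_xy([r for r in dataset.records if r.replicate == 1]),
        config=final_cfg, input_norm=data.input_norm, output_norm=data.output_norm,
        extra_normalized=(data.X_train[:data.n_augmented],
                          data.Y_train[:data.n_augmented]))
    model = surro.fit(seed=seed_train)
    from .surrogate import _forward  # internal forward pass for normalized metrics
    Pte, _ = _forward(model.weights, data.X_test, 4, model.hidden_units, 4)
    test_metrics = evaluate_metrics(Pte, data.Y_test)
    rel_err = mean_relative_error(model, test_records)
    report.surrogate = _stamp({
        "hidden_units": best_h,
        "n_train": int(Xtr.shape[0]), "n_test": int(data.X_test.shape[0]),
        "test_mse": test_metrics.mse, "test_r2": test_metrics.r2,
        "mean_relative_error": rel_err,
        "gamma": model.gamma,
        "training": model.training,
    }, chash)
    if outdir:
        model.to_json(outdir / "surrogate.json")
    logger.info("train-surrogate: h=%d, test R2=%.3f in %.2fs",
                best_h, test_metrics.r2, time.perf_counter() - t0)

    # --- stage 4: GA optimization ---------------------------------------
    t0 = time.perf_counter()
    ga_cfg = replace(cfg.ga, seed=seed_ga)
    result = optimize_formulation(model, ga_cfg)
    bf = result.best_formulation
    pred = model.predict_array(result.best_x[None, :])[0]
    terms = fitness_terms(pred[2], pred[0], pred[1], pred[3]).ravel()
    report.optimization = _stamp({
        "best_chromosome": {
            "feeding_ratio": bf.feeding_ratio, "cs_percent": bf.cs_percent,
            "np_percent": bf.np_percent, "drug_percent": bf.drug_percent},
        "best_fitness": result.best_fitness,
        "predicted_response": {"br": pred[0], "trmax": pred[1],
                               "rtrmax": pred[2], "le": pred[3]},
        "fitness_terms": {"rtrmax": float(terms[0]), "br": float(terms[1]),
                          "trmax": float(terms[2]), "le": float(terms[3])},
        "stopping_reason": result.stopping_reason,
        "n_runs": len(result.runs) if result.runs else 1,
        "per_run_fitness": [r.best_fitness for r in (result.runs or [result])],
    }, chash)
    logger.info("optimize: best fitness %.4f in %.2fs", result.best_fitness,
                time.perf_counter() - t0)

    if outdir:
        report.to_json(outdir / "report.json")
    return report


def report_render(report: PipelineReport) -> str:
    """Markdown summary of a pipeline report.

    Incomplete reports list their missing sections; artifacts from mixed
    configurations are refused.
    """
    hashes = {s: getattr(report, s)["config_hash"]
              for s in report.SECTIONS if getattr(report, s) is not None}
    if any(h != report.config_hash for h in hashes.values()):
        raise ValidationError(f"mixed-provenance artifacts: {hashes} "
                              f"vs report hash {report.config_hash}")

    lines = [f"# Pipeline report (seed {report.seed}, config {report.config_hash})", ""]
    missing = report.missing_sections()
    for name in missing:
        lines.append(f"missing: {name}")
    if missing:
        lines.append("")

    if report.dataset:
        d = report.dataset
        lines += [f"## Dataset", f"- {d['n_records']} records "
                  f"({d['replicates']} replicates x 18 runs), seed {d['seed']}", ""]
    if report.kinetics:
        best = pd.DataFrame(report.kinetics["per_run"])
        if not best.empty:
            counts = best["best_model"].value_counts().to_dict()
            lines += ["## Kinetics", f"- best model counts: {counts}", ""]
    if report.sweep:
        lines += ["## Hidden-unit sweep",
                  f"- selected {report.sweep['best_hidden_units']} hidden units", ""]
    if report.comparison:
        c = report.comparison
        lines += ["## Small-data strategy",
                  f"- Gaussian noise: MSE {c['gaussian_noise']['mse']:.4f}, "
                  f"R2 {c['gaussian_noise']['r2']:.3f}",
                  f"- {10}-fold CV: MSE {c['cross_validation']['mse']:.4f}, "
                  f"R2 {c['cross_validation']['r2']:.3f}",
                  f"- winner: {c['winner']}", ""]
    if report.surrogate:
        s = report.surrogate
        lines += ["## Surrogate",
                  f"- test MSE {s['test_mse']:.4f}, test R2 {s['test_r2']:.3f}, "
                  f"mean relative error {100 * s['mean_relative_error']:.1f}%",
                  f"- effective parameters gamma = {s['gamma']:.1f}", ""]
    if report.optimization:
        o = report.optimization
        ch = o["best_chromosome"]
        ft = o["fitness_terms"]
        lines += ["## Optimization",
                  f"- best chromosome: feeding {ch['feeding_ratio']:.3f}, "
                  f"CS {ch['cs_percent']:.2f}%, Fe3O4 {ch['np_percent']:.2f}%, "
                  f"5FU {ch['drug_percent']:.2f}%",
                  f"- best fitness {o['best_fitness']:.4f} "
                  f"({o['n_runs']} runs, stop: {o['stopping_reason']})",
                  "- fitness decomposition: "
                  f"RTRmax {ft['rtrmax']:.4f} + BR {ft['br']:.4f} + "
                  f"TRmax {ft['trmax']:.4f} + Le {ft['le']:.4f}", ""]
    return "\n".join(lines)
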